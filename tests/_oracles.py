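"""Independent oracle implementations used by the test suite.

These deliberately avoid the code paths they check: RMSD via SVD (Kabsch)
instead of the quaternion polynomial, and match enumeration by plain
recursion instead of the compiled search kernel.
"""

import numpy as np

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent optimal proper-rotation RMSD via SVD (Kabsch).

    Used as the oracle against the quaternion implementation; reflections
    are excluded by the determinant sign correction.
    """
    from scipy.linalg import svd

    a = np.asarray(a, float).reshape(-1, 3)
    b = np.asarray(b, float).reshape(-1, 3)
    x = a - a.mean(axis=0)
    y = b - b.mean(axis=0)
    h = y.T @ x
    u, s, vt = svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s_corr = s.copy()
    s_corr[-1] *= d
    err = (x * x).sum() + (y * y).sum() - 2.0 * s_corr.sum()
    return float(np.sqrt(max(err, 0.0) / len(a)))


def brute_force_maxima(seed_list, threshold):
    """Exhaustive enumeration of maximal matches by breadth-first closure.

    ``seed_list`` holds (unit_a, unit_b, coords_a, coords_b) tuples.  A pair
    set is admissible when some insertion order keeps every intermediate
    subset at or below the threshold: starting from admissible singletons,
    every admissible set of size L is extended by every non-conflicting
    seed, keeping extensions whose Kabsch RMSD passes; duplicates collapse
    via frozensets.  Returns the maximum size and the maximal sets with
    their RMSDs.
    """
    n = len(seed_list)

    def coords_of(members):
        ca = np.concatenate([seed_list[i][2] for i in sorted(members)])
        cb = np.concatenate([seed_list[i][3] for i in sorted(members)])
        return ca, cb

    frontier = set()
    for s in range(n):
        if kabsch_rmsd(seed_list[s][2], seed_list[s][3]) <= threshold:
            frontier.add(frozenset([s]))
    if not frontier:
        return 0, []
    last = frontier
    while True:
        children = set()
        for members in last:
            used_a = {seed_list[i][0] for i in members}
            used_b = {seed_list[i][1] for i in members}
            for c in range(n):
                if c in members:
                    continue
                if seed_list[c][0] in used_a or seed_list[c][1] in used_b:
                    continue
                child = members | {c}
                if child in children:
                    continue
                ca, cb = coords_of(child)
                if kabsch_rmsd(ca, cb) <= threshold:
                    children.add(child)
        if not children:
            break
        last = children
    out = []
    for members in sorted(last, key=sorted):
        ca, cb = coords_of(members)
        out.append((tuple(sorted(members)), kabsch_rmsd(ca, cb)))
    best = len(next(iter(last)))
    return best, out
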