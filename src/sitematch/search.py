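"""Branch-and-bound search for maximal superimposable correspondences.

The search starts from every single-unit pairing the equivalence rules
allow and grows partial matches one unit pair at a time.  A partial match
is kept only while its pseudoatoms superimpose — under the optimal proper
rigid motion — with an RMSD at or below the threshold.  A match is a *set*
of unit pairs: a set is admissible when some insertion order keeps every
intermediate partial match under the threshold, and sets reachable through
different insertion orders are collapsed, so each admissible set is
evaluated exactly once.  The enumeration is level-synchronous (all
admissible sets of size L are extended together), which makes the result
independent of input order and symmetric under swapping the two
structures.  When the exploration finishes, all matches of maximum size
are returned.

Extensions are pre-screened with inter-point distance bounds implied by
the RMSD criterion itself: any superposition of n points with rmsd <= t
satisfies |d_a - d_b| <= t*sqrt(2n) for every point pair, and
sum_{i<j} (d_a(i,j) - d_b(i,j))^2 <= 2 n (n-1) t^2 over all pairs.  The
pre-screen never rejects an extension the criterion would admit; surviving
extensions are evaluated exactly with the quaternion characteristic
polynomial (largest eigenvalue by Newton iteration, with a bisection
fallback for degenerate cases).  The hot loop is compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba
import numpy as np

from .pseudoatoms import PseudoatomSet
from .representation import Representation, allowed_pairings
from .superpose import Superposition, optimal_superposition

__all__ = [
    "SearchParams",
    "Match",
    "SearchBudgetError",
    "seed_pairs",
    "find_matches",
]

_MAX_SEEDS = 20000  # the pairwise bound matrix above this would not fit memory
_MAX_TIES = 2_000_000  # partial matches per level before aborting (memory guard)


class SearchBudgetError(RuntimeError):
    """The search exceeded the configured node budget (or seed capacity)."""


@dataclass(frozen=True)
class SearchParams:
    rmsd_threshold: float = 0.7
    min_report_size: int = 3
    node_budget: int = 10**8
    max_solutions: int | None = None

    def __post_init__(self):
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be > 0")
        if self.min_report_size < 1:
            raise ValueError("min_report_size must be >= 1")


@dataclass(frozen=True)
class CandidatePair:
    """One admissible unit-to-unit pairing (a seed of the search)."""

    index: int
    unit_a: int  # position in set_a.units
    unit_b: int
    recipe_pairs: tuple[tuple[str, str], ...]  # pseudoatom pairing, in order
    coords_a: np.ndarray  # (k, 3)
    coords_b: np.ndarray


@dataclass(frozen=True)
class Match:
    """An injective unit correspondence with its optimal superposition."""

    pairs: tuple[tuple[int, int, tuple[tuple[str, str], ...]], ...]
    superposition: Superposition
    size_units: int
    size_pseudoatoms: int
    residue_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def rmsd(self) -> float:
        return self.superposition.rmsd


def seed_pairs(
    set_a: PseudoatomSet, set_b: PseudoatomSet, rep: Representation
) -> list[CandidatePair]:
    """All single-unit pairings allowed by the representation's rules.

    One seed per (unit_a, unit_b, correspondence) triple, ordered by a-unit
    then b-unit then correspondence; each correspondence is restricted to
    recipe pairs whose pseudoatoms are present on both sides.
    """
    seeds: list[CandidatePair] = []
    pairing_cache: dict[tuple[str, str], list[tuple[tuple[str, str], ...]]] = {}

    def pairings(res_a: str, res_b: str):
        key = (res_a, res_b)
        if key not in pairing_cache:
            pairing_cache[key] = allowed_pairings(res_a, res_b, rep)
        return pairing_cache[key]

    for ia, ua in enumerate(set_a.units):
        for ib, ub in enumerate(set_b.units):
            corrs = pairings(ua.residue_name, ub.residue_name)
            if not corrs:
                continue
            if set_a.independent:
                ka, kb = ua.recipe_key, ub.recipe_key
                if any((ka, kb) == pair for corr in corrs for pair in corr):
                    pa, pb = ua.pseudoatoms[0], ub.pseudoatoms[0]
                    seeds.append(
                        CandidatePair(
                            index=len(seeds),
                            unit_a=ia,
                            unit_b=ib,
                            recipe_pairs=((pa.recipe_name, pb.recipe_name),),
                            coords_a=pa.coords.reshape(1, 3),
                            coords_b=pb.coords.reshape(1, 3),
                        )
                    )
                continue
            seen = set()
            for corr in corrs:
                concrete = []
                ca, cb = [], []
                for ra, rb in corr:
                    pa, pb = ua.get(ra), ub.get(rb)
                    if pa is None or pb is None:
                        continue  # atom missing in the coordinates
                    concrete.append((ra, rb))
                    ca.append(pa.coords)
                    cb.append(pb.coords)
                key = tuple(concrete)
                if not concrete or key in seen:
                    continue
                seen.add(key)
                seeds.append(
                    CandidatePair(
                        index=len(seeds),
                        unit_a=ia,
                        unit_b=ib,
                        recipe_pairs=key,
                        coords_a=np.array(ca),
                        coords_b=np.array(cb),
                    )
                )
    return seeds


def _pair_bound_matrix(seeds: list[CandidatePair]) -> np.ndarray:
    """delta[s, t] = max over point combos of | d_a - d_b | for seeds s, t."""
    ns = len(seeds)
    kmax = max(len(s.coords_a) for s in seeds)
    a = np.full((ns, kmax, 3), np.nan, dtype=np.float32)
    b = np.full((ns, kmax, 3), np.nan, dtype=np.float32)
    for i, s in enumerate(seeds):
        a[i, : len(s.coords_a)] = s.coords_a
        b[i, : len(s.coords_b)] = s.coords_b
    delta = np.zeros((ns, ns), dtype=np.float32)
    for i in range(kmax):
        for j in range(kmax):
            da = np.linalg.norm(a[:, None, i, :] - a[None, :, j, :], axis=-1)
            db = np.linalg.norm(b[:, None, i, :] - b[None, :, j, :], axis=-1)
            diff = np.abs(da - db)
            np.nan_to_num(diff, copy=False, nan=0.0)
            np.maximum(delta, diff, out=delta)
    return delta


@numba.njit(cache=True, inline="always")
def _qcp_rmsd_from_stats(
    n, sax, say, saz, sbx, sby, sbz, qa, qb,
    m00, m01, m02, m10, m11, m12, m20, m21, m22,
):
    """RMSD of the optimal proper superposition from sufficient statistics.

    ``m00..m22`` are the raw (uncentered) sums of outer(b_i, a_i); the largest
    eigenvalue of the quaternion key matrix is the largest root of the
    depressed quartic L^4 + c2 L^2 + c1 L + c0, found by Newton iteration
    from the upper bound (Ga+Gb)/2 with a bisection fallback.
    """
    fn = float(n)
    sxx = m00 - sbx * sax / fn
    sxy = m01 - sbx * say / fn
    sxz = m02 - sbx * saz / fn
    syx = m10 - sby * sax / fn
    syy = m11 - sby * say / fn
    syz = m12 - sby * saz / fn
    szx = m20 - sbz * sax / fn
    szy = m21 - sbz * say / fn
    szz = m22 - sbz * saz / fn
    ga = qa - (sax * sax + say * say + saz * saz) / fn
    gb = qb - (sbx * sbx + sby * sby + sbz * sbz) / fn

    c2 = -2.0 * (
        sxx * sxx + sxy * sxy + sxz * sxz
        + syx * syx + syy * syy + syz * syz
        + szx * szx + szy * szy + szz * szz
    )
    c1 = 8.0 * (
        sxx * syz * szy + syy * szx * sxz + szz * sxy * syx
        - sxx * syy * szz - syz * szx * sxy - szy * syx * sxz
    )
    sxzpszx = sxz + szx
    syzpszy = syz + szy
    sxypsyx = sxy + syx
    syzmszy = syz - szy
    sxzmszx = sxz - szx
    sxymsyx = sxy - syx
    sxxpsyy = sxx + syy
    sxxmsyy = sxx - syy
    d1 = sxy * sxy + sxz * sxz - syx * syx - szx * szx
    d2 = 2.0 * (syz * szy - syy * szz)
    d3 = syy * syy + szz * szz - sxx * sxx + syz * syz + szy * szy
    c0 = (
        d1 * d1
        + (d3 + d2) * (d3 - d2)
        + (-sxzpszx * syzmszy + sxymsyx * (sxxmsyy - szz))
        * (-sxzmszx * syzpszy + sxymsyx * (sxxmsyy + szz))
        + (-sxzpszx * syzpszy - sxypsyx * (sxxpsyy - szz))
        * (-sxzmszx * syzmszy - sxypsyx * (sxxpsyy + szz))
        + (sxypsyx * syzpszy + sxzpszx * (sxxmsyy + szz))
        * (-sxymsyx * syzmszy + sxzpszx * (sxxpsyy + szz))
        + (sxypsyx * syzmszy + sxzmszx * (sxxmsyy - szz))
        * (-sxymsyx * syzpszy + sxzmszx * (sxxpsyy - szz))
    )

    e0 = 0.5 * (ga + gb)
    lam = e0
    tol = 1e-11 * (e0 if e0 > 1.0 else 1.0)
    ok = False
    for _ in range(60):
        lam2 = lam * lam
        p = lam2 * lam2 + c2 * lam2 + c1 * lam + c0
        # at a degenerate (multiple) root the derivative vanishes; accept when
        # the residual is at rounding-noise level relative to its terms
        p_scale = abs(lam2 * lam2) + abs(c2 * lam2) + abs(c1 * lam) + abs(c0) + 1.0
        if abs(p) <= 1e-12 * p_scale:
            ok = True
            break
        dp = 4.0 * lam2 * lam + 2.0 * c2 * lam + c1
        if dp == 0.0:
            break
        step = p / dp
        lam -= step
        if abs(step) <= tol:
            ok = True
            break
    if not ok:
        # bisection between -e0-1 and e0; if no sign change exists the value
        # collapses toward the lower end, overestimating the RMSD of what is
        # a hopeless superposition anyway
        lo = -e0 - 1.0
        hi = e0
        for _ in range(120):
            mid = 0.5 * (lo + hi)
            lam2 = mid * mid
            p = lam2 * lam2 + c2 * lam2 + c1 * mid + c0
            if p > 0.0:
                hi = mid
            else:
                lo = mid
        lam = 0.5 * (lo + hi)
    err = ga + gb - 2.0 * lam
    if err < 0.0:
        err = 0.0
    return math.sqrt(err / fn)


@numba.njit(cache=True)
def _rmsd_of_rows(rows, npts, sa, sb, qa, qb, mab):
    """Batched RMSD for sets of seeds (one row of seed ids per set)."""
    nr, width = rows.shape
    out = np.empty(nr, np.float64)
    for r in range(nr):
        n = 0
        ax = ay = az = bx = by = bz = 0.0
        xqa = 0.0
        xqb = 0.0
        m00 = m01 = m02 = m10 = m11 = m12 = m20 = m21 = m22 = 0.0
        for j in range(width):
            s = rows[r, j]
            n += npts[s]
            ax += sa[s, 0]
            ay += sa[s, 1]
            az += sa[s, 2]
            bx += sb[s, 0]
            by += sb[s, 1]
            bz += sb[s, 2]
            xqa += qa[s]
            xqb += qb[s]
            m00 += mab[s, 0, 0]
            m01 += mab[s, 0, 1]
            m02 += mab[s, 0, 2]
            m10 += mab[s, 1, 0]
            m11 += mab[s, 1, 1]
            m12 += mab[s, 1, 2]
            m20 += mab[s, 2, 0]
            m21 += mab[s, 2, 1]
            m22 += mab[s, 2, 2]
        out[r] = _qcp_rmsd_from_stats(
            n, ax, ay, az, bx, by, bz, xqa, xqb,
            m00, m01, m02, m10, m11, m12, m20, m21, m22,
        )
    return out


@numba.njit(cache=True)
def _search_levels(
    npts, sa, sb, qa, qb, mab,  # per-seed sufficient statistics
    delta,  # (N, N) float32; +inf where two seeds conflict
    thr, loose, node_budget, max_ties,
):
    """Level-synchronous closure over admissible pair sets.

    Level L holds every admissible set of L seeds (reachable by some
    insertion order with all intermediate sets admissible), as sorted seed
    rows.  Extensions of a state are drawn from the candidate list of its
    width-2 ancestor (materialised once), screened inline against the
    members added since with the distance-deviation bounds the RMSD
    criterion implies; duplicates collapse through an open-addressing hash
    with full row verification; survivors of the exact RMSD test form the
    next level.  Returns the last non-empty level, the explored-state
    count, and an error flag (0 ok, 1 node budget, 2 level size).
    """
    n_seeds = npts.shape[0]

    # ---- width 1: admissible singletons
    singles = np.empty((n_seeds, 1), np.int32)
    n1 = 0
    for s in range(n_seeds):
        r = _qcp_rmsd_from_stats(
            npts[s], sa[s, 0], sa[s, 1], sa[s, 2],
            sb[s, 0], sb[s, 1], sb[s, 2], qa[s], qb[s],
            mab[s, 0, 0], mab[s, 0, 1], mab[s, 0, 2],
            mab[s, 1, 0], mab[s, 1, 1], mab[s, 1, 2],
            mab[s, 2, 0], mab[s, 2, 1], mab[s, 2, 2],
        )
        if r <= thr:
            singles[n1, 0] = s
            n1 += 1
    level1 = singles[:n1].copy()
    explored = n_seeds
    if explored > node_budget:
        return level1, explored, 1
    if n1 == 0:
        return level1, explored, 0

    # ---- root candidate lists (count, then fill)
    root_off = np.empty(n1 + 1, np.int64)
    k = 0
    for i in range(n1):
        s = level1[i, 0]
        root_off[i] = k
        for c in range(n_seeds):
            if delta[s, c] <= loose:
                k += 1
    root_off[n1] = k
    root_c = np.empty(k, np.int32)
    root_d = np.empty(k, np.float32)
    k = 0
    for i in range(n1):
        s = level1[i, 0]
        for c in range(n_seeds):
            d = delta[s, c]
            if d <= loose:
                root_c[k] = c
                root_d[k] = d
                k += 1

    # ---- width 2: pairs from root lists
    n_emit = 0
    for i in range(n1):
        s = level1[i, 0]
        base = npts[s]
        for idx in range(root_off[i], root_off[i + 1]):
            c = root_c[idx]
            n_new = float(base + npts[c])
            d = float(root_d[idx])
            if d > thr * math.sqrt(2.0 * n_new) + 1e-9:
                continue
            if d * d > 2.0 * n_new * (n_new - 1.0) * thr * thr + 1e-9:
                continue
            n_emit += 1
    if n_emit == 0:
        return level1, explored, 0
    rows2 = np.empty((n_emit, 2), np.int32)
    tot2 = np.empty(n_emit, np.float64)
    e = 0
    for i in range(n1):
        s = level1[i, 0]
        base = npts[s]
        for idx in range(root_off[i], root_off[i + 1]):
            c = root_c[idx]
            n_new = float(base + npts[c])
            d = float(root_d[idx])
            if d > thr * math.sqrt(2.0 * n_new) + 1e-9:
                continue
            if d * d > 2.0 * n_new * (n_new - 1.0) * thr * thr + 1e-9:
                continue
            if s < c:
                rows2[e, 0] = s
                rows2[e, 1] = c
            else:
                rows2[e, 0] = c
                rows2[e, 1] = s
            tot2[e] = d * d
            e += 1
    uniq2, n_u2 = _dedup_rows(rows2)
    explored += n_u2
    if explored > node_budget:
        return level1, explored, 1
    level = np.empty((n_u2, 2), np.int32)
    const = np.empty(n_u2, np.float64)
    n2 = 0
    for u in range(n_u2):
        i = uniq2[u]
        r = _rmsd_of_pairset(rows2, i, 2, npts, sa, sb, qa, qb, mab)
        if r <= thr:
            level[n2, 0] = rows2[i, 0]
            level[n2, 1] = rows2[i, 1]
            const[n2] = tot2[i]
            n2 += 1
    if n2 == 0:
        return level1, explored, 0
    level = level[:n2].copy()
    const = const[:n2].copy()
    if n2 > max_ties:
        return level, explored, 2

    # ---- width-2 ancestor lists: the pair's joint candidates (exact size)
    l2_off = np.empty(n2 + 1, np.int64)
    k = 0
    for i in range(n2):
        s1 = level[i, 0]
        s2 = level[i, 1]
        l2_off[i] = k
        for c in range(n_seeds):
            if delta[s1, c] <= loose and delta[s2, c] <= loose:
                k += 1
    l2_off[n2] = k
    l2_c = np.empty(k, np.int32)
    l2_dmax = np.empty(k, np.float32)
    l2_dsum = np.empty(k, np.float32)
    k = 0
    for i in range(n2):
        s1 = level[i, 0]
        s2 = level[i, 1]
        for c in range(n_seeds):
            d1 = delta[s1, c]
            if d1 > loose:
                continue
            d2 = delta[s2, c]
            if d2 > loose:
                continue
            l2_c[k] = c
            l2_dmax[k] = d1 if d1 > d2 else d2
            l2_dsum[k] = d1 * d1 + d2 * d2
            k += 1

    anc = np.arange(n2, dtype=np.int64)  # width-2 ancestor of each state
    anc_s1 = level[:, 0].copy()  # seed ids of the ancestor pair
    anc_s2 = level[:, 1].copy()
    best = level

    while True:
        n_states, width = level.shape
        wnew = width + 1
        extra = width - 2  # members beyond the width-2 ancestor pair

        n_emit = 0
        for s in range(n_states):
            a2 = anc[s]
            base = 0
            for j in range(width):
                base += npts[level[s, j]]
            cs = const[s]
            s1a = anc_s1[a2]
            s2a = anc_s2[a2]
            for idx in range(l2_off[a2], l2_off[a2 + 1]):
                cc = l2_c[idx]
                n_new = float(base + npts[cc])
                bb = thr * math.sqrt(2.0 * n_new) + 1e-9
                dm = float(l2_dmax[idx])
                if dm > bb:
                    continue
                ds = float(l2_dsum[idx])
                ok = True
                for j in range(width):
                    m = level[s, j]
                    if m == s1a or m == s2a:
                        continue
                    d = float(delta[m, cc])
                    if d > bb:
                        ok = False
                        break
                    if d > dm:
                        dm = d
                    ds += d * d
                if not ok:
                    continue
                if cs + ds > 2.0 * n_new * (n_new - 1.0) * thr * thr + 1e-9:
                    continue
                n_emit += 1
        if n_emit == 0:
            break
        rows = np.empty((n_emit, wnew), np.int32)
        tot = np.empty(n_emit, np.float64)
        panc = np.empty(n_emit, np.int64)
        e = 0
        for s in range(n_states):
            a2 = anc[s]
            base = 0
            for j in range(width):
                base += npts[level[s, j]]
            cs = const[s]
            s1a = anc_s1[a2]
            s2a = anc_s2[a2]
            for idx in range(l2_off[a2], l2_off[a2 + 1]):
                cc = l2_c[idx]
                n_new = float(base + npts[cc])
                bb = thr * math.sqrt(2.0 * n_new) + 1e-9
                dm = float(l2_dmax[idx])
                if dm > bb:
                    continue
                ds = float(l2_dsum[idx])
                ok = True
                for j in range(width):
                    m = level[s, j]
                    if m == s1a or m == s2a:
                        continue
                    d = float(delta[m, cc])
                    if d > bb:
                        ok = False
                        break
                    if d > dm:
                        dm = d
                    ds += d * d
                if not ok:
                    continue
                t = cs + ds
                if t > 2.0 * n_new * (n_new - 1.0) * thr * thr + 1e-9:
                    continue
                pos = 0
                while pos < width and level[s, pos] < cc:
                    rows[e, pos] = level[s, pos]
                    pos += 1
                rows[e, pos] = cc
                for j in range(pos, width):
                    rows[e, j + 1] = level[s, j]
                tot[e] = t
                panc[e] = a2
                e += 1

        uniq, n_uniq = _dedup_rows(rows)
        explored += n_uniq
        if explored > node_budget:
            return best, explored, 1

        new_level = np.empty((n_uniq, wnew), np.int32)
        new_const = np.empty(n_uniq, np.float64)
        new_anc = np.empty(n_uniq, np.int64)
        n_kept = 0
        for u in range(n_uniq):
            i = uniq[u]
            r = _rmsd_of_pairset(rows, i, wnew, npts, sa, sb, qa, qb, mab)
            if r <= thr:
                for j in range(wnew):
                    new_level[n_kept, j] = rows[i, j]
                new_const[n_kept] = tot[i]
                new_anc[n_kept] = panc[i]
                n_kept += 1
        if n_kept == 0:
            break
        if n_kept > max_ties:
            return best, explored, 2
        level = new_level[:n_kept].copy()
        const = new_const[:n_kept].copy()
        anc = new_anc[:n_kept].copy()
        best = level

    return best, explored, 0


@numba.njit(cache=True, inline="always")
def _rmsd_of_pairset(rows, i, width, npts, sa, sb, qa, qb, mab):
    n = 0
    ax = ay = az = bx = by = bz = 0.0
    xqa = 0.0
    xqb = 0.0
    m00 = m01 = m02 = m10 = m11 = m12 = m20 = m21 = m22 = 0.0
    for j in range(width):
        s = rows[i, j]
        n += npts[s]
        ax += sa[s, 0]
        ay += sa[s, 1]
        az += sa[s, 2]
        bx += sb[s, 0]
        by += sb[s, 1]
        bz += sb[s, 2]
        xqa += qa[s]
        xqb += qb[s]
        m00 += mab[s, 0, 0]
        m01 += mab[s, 0, 1]
        m02 += mab[s, 0, 2]
        m10 += mab[s, 1, 0]
        m11 += mab[s, 1, 1]
        m12 += mab[s, 1, 2]
        m20 += mab[s, 2, 0]
        m21 += mab[s, 2, 1]
        m22 += mab[s, 2, 2]
    return _qcp_rmsd_from_stats(
        n, ax, ay, az, bx, by, bz, xqa, xqb,
        m00, m01, m02, m10, m11, m12, m20, m21, m22,
    )


@numba.njit(cache=True)
def _dedup_rows(rows):
    """First-occurrence indices of unique rows (open addressing + verify)."""
    n, width = rows.shape
    tsize = 1
    while tsize < 2 * n:
        tsize *= 2
    mask = tsize - 1
    table = np.full(tsize, -1, np.int64)
    out = np.empty(n, np.int64)
    n_out = 0
    for i in range(n):
        h = numba.uint64(1469598103934665603)
        for j in range(width):
            h = (h ^ numba.uint64(rows[i, j])) * numba.uint64(1099511628211)
        slot = numba.int64(h & numba.uint64(mask))
        dup = False
        while True:
            other = table[slot]
            if other < 0:
                table[slot] = i
                break
            same = True
            for j in range(width):
                if rows[other, j] != rows[i, j]:
                    same = False
                    break
            if same:
                dup = True
                break
            slot = (slot + 1) & mask
        if not dup:
            out[n_out] = i
            n_out += 1
    return out, n_out


def find_matches(
    set_a: PseudoatomSet,
    set_b: PseudoatomSet,
    rep: Representation,
    params: SearchParams | None = None,
) -> list[Match]:
    """All maximum-size unit correspondences under the RMSD threshold.

    Returns every maximal match (ties included, deduplicated by unordered
    pair set), sorted by RMSD ascending then lexicographic pair order;
    matches smaller than ``params.min_report_size`` are suppressed.  Empty
    inputs give an empty result.  Raises :class:`SearchBudgetError` when
    the number of evaluated partial matches exceeds ``params.node_budget``
    or the seed pairing list exceeds memory capacity.
    """
    params = params or SearchParams()
    seeds = seed_pairs(set_a, set_b, rep)
    if not seeds:
        return []
    if len(seeds) > _MAX_SEEDS:
        raise SearchBudgetError(
            f"{len(seeds)} seed pairings exceed the {_MAX_SEEDS} capacity; "
            "narrow the selections or tighten the equivalence rules"
        )

    n_seeds = len(seeds)
    thr = float(params.rmsd_threshold)
    npts = np.array([len(s.coords_a) for s in seeds], dtype=np.int64)
    sa = np.zeros((n_seeds, 3))
    sb = np.zeros((n_seeds, 3))
    qa = np.zeros(n_seeds)
    qb = np.zeros(n_seeds)
    mab = np.zeros((n_seeds, 3, 3))
    for i, s in enumerate(seeds):
        a, b = s.coords_a, s.coords_b
        sa[i] = a.sum(axis=0)
        sb[i] = b.sum(axis=0)
        qa[i] = (a * a).sum()
        qb[i] = (b * b).sum()
        mab[i] = b.T @ a
    ia_arr = np.array([s.unit_a for s in seeds])
    ib_arr = np.array([s.unit_b for s in seeds])
    conflict = (ia_arr[:, None] == ia_arr[None, :]) | (ib_arr[:, None] == ib_arr[None, :])
    delta = _pair_bound_matrix(seeds)
    delta[conflict] = np.float32(1e30)  # conflicting seeds can never coexist

    # loosest pair bound any match could require: a pair of seeds inside a
    # match of n points satisfies delta <= thr*sqrt(2n); n is capped by the
    # smaller side's pseudoatom total
    max_pts = min(
        sum(len(u.pseudoatoms) for u in set_a.units),
        sum(len(u.pseudoatoms) for u in set_b.units),
    )
    loose = np.float32(thr * math.sqrt(2.0 * max(max_pts, 2)) + 1e-9)

    best_level, _explored, flag = _search_levels(
        npts, sa, sb, qa, qb, mab, delta, thr, float(loose),
        int(params.node_budget), _MAX_TIES,
    )
    if flag == 1:
        raise SearchBudgetError(f"node budget of {params.node_budget} exceeded")
    if flag == 2:
        raise SearchBudgetError(
            f"more than {_MAX_TIES} tied partial matches; the comparison is "
            "degenerate (threshold too permissive for the representation)"
        )
    if len(best_level) == 0 or best_level.shape[1] < params.min_report_size:
        return []

    matches = []
    for row in best_level:
        chosen = [seeds[int(i)] for i in row]
        pairs = tuple(sorted((s.unit_a, s.unit_b, s.recipe_pairs) for s in chosen))
        coords_a = np.concatenate([s.coords_a for s in chosen])
        coords_b = np.concatenate([s.coords_b for s in chosen])
        sup = optimal_superposition(coords_a, coords_b)
        residue_pairs = tuple(
            (set_a.units[s.unit_a].residue_label, set_b.units[s.unit_b].residue_label)
            for s in chosen
        )
        matches.append(
            Match(
                pairs=pairs,
                superposition=sup,
                size_units=len(pairs),
                size_pseudoatoms=int(sum(len(s.coords_a) for s in chosen)),
                residue_pairs=residue_pairs,
            )
        )
    matches.sort(key=lambda m: (m.rmsd, m.pairs))
    if params.max_solutions is not None:
        matches = matches[: params.max_solutions]
    return matches
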