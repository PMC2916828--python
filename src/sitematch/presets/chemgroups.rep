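# Side-chain chemical groups, matched as independent entities.
mode independent
def ALA CB
def ARG avg(NE,CZ,NH1,NH2):GUA
def ASN avg(OD1,ND2):AMI
def ASP avg(OD1,OD2):CRX
def CYS SG
def GLN avg(OE1,NE2):AMI
def GLU avg(OE1,OE2):CRX
def GLY CA
def HIS avg(ND1,NE2):IMI avg(CG,ND1,CD2,CE1,NE2):RING
def ILE avg(CG2,CD1):ALI
def LEU avg(CD1,CD2):ALI
def LYS NZ
def MET SD
def PHE avg(CG,CD1,CD2,CE1,CE2,CZ):RING
def PRO avg(CB,CG,CD):ALI
def SER OG
def THR OG1
def TRP NE1 avg(CD2,CE2,CE3,CZ2,CZ3,CH2):RING
def TYR OH avg(CG,CD1,CD2,CE1,CE2,CZ):RING
def VAL avg(CG1,CG2):ALI
# hydroxyl / hydrogen-bonding oxygens
SER THR TYR.(OH)
# carboxylates
ASP GLU
# amides
ASN GLN
# aromatic ring centroids
PHE.(RING) TYR.(RING) TRP.(RING) HIS.(RING)
# positively chargeable / donor nitrogens
LYS ARG.(GUA) HIS.(IMI) TRP.(NE1)
# sulfur
CYS MET
# aliphatic side chains
ALA VAL.(ALI) LEU.(ALI) ILE.(ALI) PRO.(ALI)
# glycine matches glycine only
GLY
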