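# CA + side-chain centroid; substitutions restricted to BLOSUM62 >= -1.
mode grouped
def ALA CA avg(CB):SCC
def ARG CA avg(CB,CG,CD,NE,CZ,NH1,NH2):SCC
def ASN CA avg(CB,CG,OD1,ND2):SCC
def ASP CA avg(CB,CG,OD1,OD2):SCC
def CYS CA avg(CB,SG):SCC
def GLN CA avg(CB,CG,CD,OE1,NE2):SCC
def GLU CA avg(CB,CG,CD,OE1,OE2):SCC
def GLY CA avg(CA):SCC
def HIS CA avg(CB,CG,ND1,CD2,CE1,NE2):SCC
def ILE CA avg(CB,CG1,CG2,CD1):SCC
def LEU CA avg(CB,CG,CD1,CD2):SCC
def LYS CA avg(CB,CG,CD,CE,NZ):SCC
def MET CA avg(CB,CG,SD,CE):SCC
def PHE CA avg(CB,CG,CD1,CD2,CE1,CE2,CZ):SCC
def PRO CA avg(CB,CG,CD):SCC
def SER CA avg(CB,OG):SCC
def THR CA avg(CB,OG1,CG2):SCC
def TRP CA avg(CB,CG,CD1,CD2,NE1,CE2,CE3,CZ2,CZ3,CH2):SCC
def TYR CA avg(CB,CG,CD1,CD2,CE1,CE2,CZ,OH):SCC
def VAL CA avg(CB,CG1,CG2):SCC
ALA
ALA ARG
ALA CYS
ALA GLN
ALA GLU
ALA GLY
ALA ILE
ALA LEU
ALA LYS
ALA MET
ALA PRO
ALA SER
ALA THR
ALA VAL
ARG
ARG ASN
ARG GLN
ARG GLU
ARG HIS
ARG LYS
ARG MET
ARG SER
ARG THR
ASN
ASN ASP
ASN GLN
ASN GLU
ASN GLY
ASN HIS
ASN LYS
ASN SER
ASN THR
ASP
ASP GLN
ASP GLU
ASP GLY
ASP HIS
ASP LYS
ASP PRO
ASP SER
ASP THR
CYS
CYS ILE
CYS LEU
CYS MET
CYS SER
CYS THR
CYS VAL
GLN
GLN GLU
GLN HIS
GLN LYS
GLN MET
GLN PRO
GLN SER
GLN THR
GLN TYR
GLU
GLU HIS
GLU LYS
GLU PRO
GLU SER
GLU THR
GLY
GLY SER
HIS
HIS LYS
HIS PHE
HIS SER
HIS TYR
ILE
ILE LEU
ILE MET
ILE PHE
ILE THR
ILE TYR
ILE VAL
LEU
LEU MET
LEU PHE
LEU THR
LEU TYR
LEU VAL
LYS
LYS MET
LYS PRO
LYS SER
LYS THR
MET
MET PHE
MET SER
MET THR
MET TRP
MET TYR
MET VAL
PHE
PHE TRP
PHE TYR
PHE VAL
PRO
PRO SER
PRO THR
SER
SER THR
THR
THR VAL
TRP
TRP TYR
TYR
TYR VAL
VAL
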