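# Compartmentalized central-carbon network for activated CD4+ T cells.
# Documented reconstruction: glycolysis, G3P shunt, LDH, ALT, pyruvate
# compartmentation (cytosol/mitochondrion) with extraction mixing, PDH,
# TCA cycle with succinate/fumarate rotational symmetry (50/50 atom-map
# variants), pyruvate carboxylase anaplerosis, malic enzyme,
# glutamine/glutamate metabolism, and dilution terms for unlabeled CO2
# and extracellular pyruvate exchange.
#
# Compartment suffixes: .x extracellular, .c cytosol, .m mitochondrion,
# .u unlabeled source, .obs measurement pool.
# Flux units: nmol / (1e6 cells) / h.

[metabolites]
GLC.x   carbons=6  balanced=no
GLN.x   carbons=5  balanced=no
PYR.x   carbons=3  balanced=no
LAC.x   carbons=3  balanced=no
GLU.x   carbons=5  balanced=no
ASP.x   carbons=4  balanced=no
CO2.u   carbons=1  balanced=no
CO2.x   carbons=1  balanced=no
G6P.c   carbons=6  balanced=yes
F6P.c   carbons=6  balanced=yes
FBP.c   carbons=6  balanced=yes
DHAP.c  carbons=3  balanced=yes
GAP.c   carbons=3  balanced=yes
PG3.c   carbons=3  balanced=yes
PEP.c   carbons=3  balanced=yes
PYR.c   carbons=3  balanced=yes
PYR.m   carbons=3  balanced=yes
PYR.obs carbons=3  balanced=no
LAC.c   carbons=3  balanced=yes
ALA.c   carbons=3  balanced=yes
G3P.c   carbons=3  balanced=yes
ACA.m   carbons=2  balanced=yes
CIT.m   carbons=6  balanced=yes
AKG.m   carbons=5  balanced=yes
GLU.m   carbons=5  balanced=yes
GLN.c   carbons=5  balanced=yes
SUC.m   carbons=4  balanced=yes
FUM.m   carbons=4  balanced=yes
MAL.m   carbons=4  balanced=yes
OAA.m   carbons=4  balanced=yes
ASP.m   carbons=4  balanced=yes
CO2.m   carbons=1  balanced=yes

[reactions]
# glycolysis
hk:      GLC.x (abcdef) -> G6P.c (abcdef)
pgi:     G6P.c (abcdef) -> F6P.c (abcdef)
pfk:     F6P.c (abcdef) -> FBP.c (abcdef)
ald:     FBP.c (abcdef) -> DHAP.c (cba) + GAP.c (def)
tpi:     DHAP.c (abc) -> GAP.c (cba)
gapdh:   GAP.c (abc) -> PG3.c (abc)
eno:     PG3.c (abc) -> PEP.c (abc)
pk:      PEP.c (abc) -> PYR.c (abc)
# glycerol-3-phosphate shunt (measurement pool fed by exchange)
g3pdh:   DHAP.c (abc) -> G3P.c (abc)  reversible
# lactate and alanine
ldh:     PYR.c (abc) -> LAC.c (abc)  reversible
lac_out: LAC.c (abc) -> LAC.x (abc)  kind=transport
alt:     PYR.c (abc) -> ALA.c (abc)  reversible
# extracellular pyruvate exchange (uptake + labeling dilution)
pyrx:    PYR.x (abc) -> PYR.c (abc)  reversible  kind=dilution
# pyruvate compartmentation
mpc:     PYR.c (abc) -> PYR.m (abc)  kind=transport
mix_pyr: PYR.c (abc) + PYR.m (abc) -> PYR.obs (abc)  kind=mixing
# pyruvate dehydrogenase and TCA cycle
pdh:     PYR.m (abc) -> CO2.m (a) + ACA.m (bc)
cs:      ACA.m (ab) + OAA.m (cdef) -> CIT.m (cdebaf)
idh:     CIT.m (abcdef) -> AKG.m (abcde) + CO2.m (f)
akgdh:   AKG.m (abcde) -> SUC.m (bcde) + CO2.m (a)
sdh:     SUC.m (abcd) -> FUM.m (abcd)  reversible
sdh:     SUC.m (abcd) -> FUM.m (dcba)  reversible
fh:      FUM.m (abcd) -> MAL.m (abcd)  reversible
fh:      FUM.m (abcd) -> MAL.m (dcba)  reversible
mdh:     MAL.m (abcd) -> OAA.m (abcd)  reversible
# anaplerosis and cataplerosis
pc:      PYR.m (abc) + CO2.m (d) -> OAA.m (abcd)
me:      MAL.m (abcd) -> PYR.m (abc) + CO2.m (d)
got:     OAA.m (abcd) -> ASP.m (abcd)  reversible
asp_out: ASP.m (abcd) -> ASP.x (abcd)
# glutamine / glutamate
gdh:     AKG.m (abcde) -> GLU.m (abcde)  reversible
gls:     GLN.c (abcde) -> GLU.m (abcde)
gs:      GLU.m (abcde) -> GLN.c (abcde)
glu_out: GLU.m (abcde) -> GLU.x (abcde)
gln_upt: GLN.x (abcde) -> GLN.c (abcde)  kind=transport
# CO2 dilution and release
co2d:    CO2.u (a) -> CO2.m (a)  kind=dilution
co2_out: CO2.m (a) -> CO2.x (a)
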