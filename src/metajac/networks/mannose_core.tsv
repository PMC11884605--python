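# Core mannose / glycolysis / glycosylation branch network.
#
# Mannose is taken up (constant inflow) and phosphorylated by hexokinase to
# mannose-6-phosphate (M6P). M6P is isomerized (reversibly) to
# fructose-6-phosphate (F6P) by phosphomannose isomerase (PMI), feeding
# glycolysis via phosphofructokinase-1 (PFK1 -> FBP), or converted
# (reversibly) to mannose-1-phosphate (M1P) by phosphomannomutase (PMM).
# GDP-mannose pyrophosphorylase (GPP) consumes M1P to make GDP-mannose, the
# donor for N-glycosylation; GTP is not part of the measured panel and is
# folded into the GPP rate constant. GPP carries a regulatory activation by
# M6P (modifier): metabolite-level regulation without substance consumption,
# which couples glycosylation flux to the upstream mannose pool and makes
# the local Jacobian of this branch concentration dependent. A parallel
# glucose branch (Glc -> G6P -> F6P) supplies glycolysis. FBP drains to
# lower glycolysis and GDP-mannose to glycan synthesis (first-order sinks).
#
# Rate constants are order-one per-time-unit fixture values chosen so that
# all pools equilibrate on comparable timescales; none are measured values.
#species
Man	mannose	glycosylation
M6P	mannose-6-phosphate	glycosylation
F6P	fructose-6-phosphate	glycolysis
FBP	fructose-1,6-bisphosphate	glycolysis
M1P	mannose-1-phosphate	glycosylation
GDPMan	GDP-mannose	glycosylation
Glc	glucose	glycolysis
G6P	glucose-6-phosphate	glycolysis
#reactions
HK	Man	M6P	-	1.0	glycosylation
PMI	M6P	F6P	-	0.8	glycolysis
PMIr	F6P	M6P	-	0.3	glycosylation
PFK1	F6P	FBP	-	0.7	glycolysis
PMM	M6P	M1P	-	0.6	glycosylation
PMMr	M1P	M6P	-	0.2	glycosylation
GPP	M1P	GDPMan	M6P	0.3	glycosylation
HKG	Glc	G6P	-	1.0	glycolysis
PGI	G6P	F6P	-	0.9	glycolysis
IN1	IN	Man	-	1.0	glycosylation
IN2	IN	Glc	-	0.8	glycolysis
OUT1	FBP	OUT	-	0.8	glycolysis
OUT2	GDPMan	OUT	-	0.8	glycosylation
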