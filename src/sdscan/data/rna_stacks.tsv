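# Nearest-neighbor RNA stack free energies at 37 C, kcal/mol.
# Watson-Crick stacks: Xia et al. 1998; G.U wobble stacks: Mathews/Turner
# (values as distributed with common secondary-structure engines, 0.1 kcal/mol
# resolution). One row per unique stack; the strand-complement-symmetric
# partner is derived at load time.
# Geometry: top strand 5'->3', bottom strand 3'->5', written left-to-right
# aligned under the top strand; top[0] pairs bottom[0], top[1] pairs bottom[1].
top	bottom	dg37
AA	UU	-0.93
AU	UA	-1.10
UA	AU	-1.33
CU	GA	-2.08
CA	GU	-2.11
GU	CA	-2.24
GA	CU	-2.35
CG	GC	-2.36
GG	CC	-3.26
GC	CG	-3.42
CU	GG	-2.10
CG	GU	-1.40
GU	CG	-2.50
GG	CU	-1.50
GU	UG	1.30
UG	GU	0.30
GG	UU	-0.50
GU	UA	-1.40
GA	UU	-1.30
AG	UU	-0.60
UA	GU	-1.00
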