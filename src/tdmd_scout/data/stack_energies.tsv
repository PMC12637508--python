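pair5p	pair3p	dg_kcal_mol
AU	AU	-0.93
AU	UA	-1.10
AU	GC	-2.08
AU	CG	-2.24
AU	GU	-0.80
AU	UG	-0.80
UA	AU	-1.33
UA	UA	-0.93
UA	GC	-2.11
UA	CG	-2.35
UA	GU	-0.80
UA	UG	-0.80
CG	AU	-2.11
CG	UA	-2.08
CG	GC	-2.36
CG	CG	-3.26
CG	GU	-1.40
CG	UG	-1.40
GC	AU	-2.35
GC	UA	-2.24
GC	GC	-3.26
GC	CG	-3.42
GC	GU	-1.40
GC	UG	-1.40
GU	AU	-0.80
GU	UA	-0.80
GU	GC	-1.40
GU	CG	-1.40
GU	GU	-0.50
GU	UG	-0.50
UG	AU	-0.80
UG	UA	-0.80
UG	GC	-1.40
UG	CG	-1.40
UG	GU	-0.50
UG	UG	-0.50
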