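codepoint	char	replacement
00B5	µ	mu
0391	Α	alpha
0392	Β	beta
0393	Γ	gamma
0394	Δ	delta
0395	Ε	epsilon
0396	Ζ	zeta
0397	Η	eta
0398	Θ	theta
0399	Ι	iota
039A	Κ	kappa
039B	Λ	lambda
039C	Μ	mu
039D	Ν	nu
039E	Ξ	xi
039F	Ο	omicron
03A0	Π	pi
03A1	Ρ	rho
03A3	Σ	sigma
03A4	Τ	tau
03A5	Υ	upsilon
03A6	Φ	phi
03A7	Χ	chi
03A8	Ψ	psi
03A9	Ω	omega
03B1	α	alpha
03B2	β	beta
03B3	γ	gamma
03B4	δ	delta
03B5	ε	epsilon
03B6	ζ	zeta
03B7	η	eta
03B8	θ	theta
03B9	ι	iota
03BA	κ	kappa
03BB	λ	lambda
03BC	μ	mu
03BD	ν	nu
03BE	ξ	xi
03BF	ο	omicron
03C0	π	pi
03C1	ρ	rho
03C2	ς	sigma
03C3	σ	sigma
03C4	τ	tau
03C5	υ	upsilon
03C6	φ	phi
03C7	χ	chi
03C8	ψ	psi
03C9	ω	omega
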