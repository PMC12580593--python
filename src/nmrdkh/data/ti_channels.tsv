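# Well-tempered channel parameters for the Ti primitive set.
# alpha: maximum exponent (bohr^-2, from MCDF innermost radii via alpha = k^2 f^2 / (pi r^2));
# chi: geometric spacing ratio; n_prim: primitive count; k, f: dimensionless channel factors.
l	alpha	chi	n_prim	k	f
s	131685.903249881	2.50	18	1	33
p	1375.44747973736	2.75	11	4/3	100
d	24.0073133461147	3.00	6	8/5	1000
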