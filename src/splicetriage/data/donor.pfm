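# 5' splice-site (donor) position frequency matrix, package-curated
# approximation of human donor-site base composition.
# offsets: -3..+6 relative to the exon|intron boundary (no position 0);
# -3..-1 are the last exonic bases, +1..+6 the first intronic bases.
# Consensus: CAG|GTAAGT
pos	A	C	G	T
-3	0.33	0.37	0.18	0.12
-2	0.60	0.13	0.14	0.13
-1	0.08	0.04	0.81	0.07
1	0.001	0.001	0.997	0.001
2	0.001	0.001	0.001	0.997
3	0.52	0.03	0.42	0.03
4	0.71	0.08	0.12	0.09
5	0.06	0.05	0.84	0.05
6	0.15	0.17	0.19	0.49
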