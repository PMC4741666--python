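# 3' splice-site (acceptor) position frequency matrix, package-curated
# approximation of human acceptor-site base composition (polypyrimidine
# tract + YAG).
# offsets: -20..+3 relative to the intron|exon boundary (no position 0);
# -20..-1 are the last intronic bases, +1..+3 the first exonic bases.
# Consensus: TTTTTTTTTTTTTTTTCCAG|GAG
pos	A	C	G	T
-20	0.13	0.30	0.12	0.45
-19	0.13	0.30	0.12	0.45
-18	0.13	0.30	0.12	0.45
-17	0.12	0.31	0.12	0.45
-16	0.12	0.31	0.12	0.45
-15	0.11	0.31	0.11	0.47
-14	0.11	0.31	0.11	0.47
-13	0.11	0.31	0.11	0.47
-12	0.10	0.31	0.11	0.48
-11	0.10	0.31	0.11	0.48
-10	0.10	0.31	0.10	0.49
-9	0.10	0.31	0.10	0.49
-8	0.10	0.32	0.09	0.49
-7	0.10	0.33	0.08	0.49
-6	0.12	0.33	0.10	0.45
-5	0.11	0.30	0.11	0.48
-4	0.24	0.28	0.24	0.24
-3	0.05	0.65	0.05	0.25
-2	0.997	0.001	0.001	0.001
-1	0.001	0.001	0.997	0.001
1	0.24	0.12	0.52	0.12
2	0.30	0.22	0.24	0.24
3	0.25	0.20	0.30	0.25
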