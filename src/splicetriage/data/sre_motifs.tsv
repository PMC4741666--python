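# Curated splicing-regulatory-element motif table (exact-match targets,
# DNA alphabet; U in the literature motif is written T here). Compact,
# user-replaceable: pass a fuller table via the motif_table config key.
factor	motif	role	provenance
hnRNP A1	TAGGGA	silencer	canonical hnRNP A1 high-affinity winner site UAGGGA (SELEX/crystallographic)
hnRNP A1	TAGGGT	silencer	canonical hnRNP A1 site UAGGGU (SELEX)
hnRNP H	TGGGGG	silencer	hnRNP H/F G-run (poly-G) silencer element
PTB	TCTTCT	silencer	PTB/hnRNP I pyrimidine-rich UCUU-class silencer
SRSF1	GAAGAA	enhancer	SRSF1 (SF2/ASF) purine-rich exonic enhancer GAR-class
Tra2beta	AAGAAC	enhancer	Tra2-beta1 AGAA-class exonic enhancer
SRSF5	ACAGCA	enhancer	SRSF5 (SRp40) exonic enhancer-class site
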