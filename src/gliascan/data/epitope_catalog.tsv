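# Non-deamidated celiac-disease epitope/peptide catalog used by gliascan.
# Peptides are the glutamine (Q) forms of HLA-DQ2.5-restricted gluten T-cell
# epitopes plus the p31-43 innate-response peptide and the protease-resistant
# 33-mer / 26-mer multi-epitope regions.  The immunogenicity_score column is an
# ILLUSTRATIVE relative scale (alpha-gliadin epitopes dominant); replace it with
# a project-specific screening table via EpitopeCatalog.from_tsv for real work.
# Entries whose sequence is shared between gliadin/hordein/secalin registries
# are kept as single rows with multi-source annotation (sec1, sec2).
epitope_id	peptide	class	immunogenicity_score	sources
DQ2.5_glia_a1a	PFPQPQLPY	alpha-DQ2.5	1.00	DQ2.5_glia_a1a
DQ2.5_glia_a1b	PYPQPQLPY	alpha-DQ2.5	0.85	DQ2.5_glia_a1b
DQ2.5_glia_a2	PQPQLPYPQ	alpha-DQ2.5	0.95	DQ2.5_glia_a2
DQ2.5_glia_a3	FRPQQPYPQ	alpha-DQ2.5	0.30	DQ2.5_glia_a3
DQ2.5_glia_g1	PQQSFPQQQ	gamma-DQ2.5	0.35	DQ2.5_glia_g1
DQ2.5_glia_g2a	IQPQQPAQL	gamma-DQ2.5	0.25	DQ2.5_glia_g2a
DQ2.5_glia_g2b	IQPQQPQQL	gamma-DQ2.5	0.25	DQ2.5_glia_g2b
DQ2.5_glia_g3	QQPQQPYPQ	gamma-DQ2.5	0.30	DQ2.5_glia_g3
DQ2.5_glia_g4a	SQPQQQFPQ	gamma-DQ2.5	0.25	DQ2.5_glia_g4a
DQ2.5_glia_g4b	PQPQQQFPQ	gamma-DQ2.5	0.25	DQ2.5_glia_g4b
DQ2.5_glia_g4c	QQPQQPFPQ	gamma-DQ2.5	0.40	DQ2.5_glia_g4c
DQ2.5_glia_g4d	SQPQQPFPQ	gamma-DQ2.5		DQ2.5_glia_g4d
DQ2.5_glia_g5	QQPFPQQPQ	gamma-DQ2.5	0.45	DQ2.5_glia_g5
DQ2.5_sec1	PFPQPQQPF	secalin-DQ2.5	0.20	DQ2.5_glia_o1;DQ2.5_hor_1;DQ2.5_sec_1
DQ2.5_sec2	PQPQQPFPQ	secalin-DQ2.5	0.20	DQ2.5_hor_2;DQ2.5_sec_2
p31_43	LGQQQPFPPQQPY	innate-peptide		p31-43
region_33mer	LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF	region-peptide		33-mer
region_26mer	FLQPQQPFPQQPQQPYPQQPQQPFPQ	region-peptide		26-mer
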