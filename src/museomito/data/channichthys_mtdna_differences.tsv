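# Published nucleotide differences between the mitochondrial genomes of
# Channichthys rhinoceratus (GenBank NC_057120, 17,408 bp) and C. rugosus.
# Bases are reference-heavy-strand; codons are printed in coding (gene)
# orientation. Empty codon fields = site outside protein-coding genes;
# empty amino-acid field = synonymous under the vertebrate mitochondrial code.
#site	ref_base	alt_base	codon_position	ref_codon	alt_codon	aa_change
1379	a	g
1552	c	t
2784	a	g
2893	a	g	3	cta	ctg
3145	g	c	3	ctg	ctc
4165	t	c	3	att	atc
4410	g	a	2	ggc	gac	G/D
4994	a	g	1	acc	gcc	T/A
5857	g	a	3	tgg	tga
7586	a	g	3	gaa	gag
8650	g	a	2	ggc	gac	G/D
9234	t	c	3	ctt	ctc
10761	g	a	3	acg	aca
11617	t	c	1	ttt	ctt	F/L
13006	t	c	3	gct	gcc
13832	g	a
14550	a	c	3	gga	ggc
15568	t	g	2	gag	gcg	E/A
15647	a	c	1	tca	gca	S/A
15831	a	g	3	gct	gcc
15882	a	g	3	tgt	tgc
15999	c	-
16049	c	t
16138	g	t
16147	g	a
16477	t	c
17347	t	c
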