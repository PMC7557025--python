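##gff-version 3
# Synthetic stand-in gene models for the six flax desaturase genes.
# Chromosome accessions and variant-site coordinates match the published
# association table; gene and exon coordinates are invented, chosen so that
# printed gene lengths (2665/2592/1137/1149/3280/3002 bp), protein lengths
# (396/396/378/382/392/391 aa) and every printed region label hold.
# Exons are the CDS (coding_offset 0).
CP027620.1	linumpool	gene	2257500	2260164	.	+	.	ID=SAD1;Name=SAD1
CP027620.1	linumpool	exon	2257500	2257896	.	+	.	ID=SAD1.e1;Parent=SAD1
CP027620.1	linumpool	exon	2259000	2259396	.	+	.	ID=SAD1.e2;Parent=SAD1
CP027620.1	linumpool	exon	2259768	2260164	.	+	.	ID=SAD1.e3;Parent=SAD1
CP027621.1	linumpool	gene	17364750	17367341	.	+	.	ID=SAD2;Name=SAD2
CP027621.1	linumpool	exon	17364900	17365296	.	+	.	ID=SAD2.e1;Parent=SAD2
CP027621.1	linumpool	exon	17365800	17366196	.	+	.	ID=SAD2.e2;Parent=SAD2
CP027621.1	linumpool	exon	17366600	17366996	.	+	.	ID=SAD2.e3;Parent=SAD2
CP027619.1	linumpool	gene	5295561	5296697	.	+	.	ID=FAD2A;Name=FAD2A
CP027619.1	linumpool	exon	5295561	5296697	.	+	.	ID=FAD2A.e1;Parent=FAD2A
CP027623.1	linumpool	gene	100000	101148	.	+	.	ID=FAD2B;Name=FAD2B
CP027623.1	linumpool	exon	100000	101148	.	+	.	ID=FAD2B.e1;Parent=FAD2B
CP027631.1	linumpool	gene	16089321	16092600	.	-	.	ID=FAD3A;Name=FAD3A
CP027631.1	linumpool	exon	16089500	16089749	.	-	.	ID=FAD3A.e6;Parent=FAD3A
CP027631.1	linumpool	exon	16090201	16090450	.	-	.	ID=FAD3A.e5;Parent=FAD3A
CP027631.1	linumpool	exon	16090900	16091149	.	-	.	ID=FAD3A.e4;Parent=FAD3A
CP027631.1	linumpool	exon	16091500	16091668	.	-	.	ID=FAD3A.e3;Parent=FAD3A
CP027631.1	linumpool	exon	16092280	16092402	.	-	.	ID=FAD3A.e2;Parent=FAD3A
CP027631.1	linumpool	exon	16092460	16092596	.	-	.	ID=FAD3A.e1;Parent=FAD3A
CP027622.1	linumpool	gene	1035200	1038201	.	+	.	ID=FAD3B;Name=FAD3B
CP027622.1	linumpool	exon	1035250	1035545	.	+	.	ID=FAD3B.e1;Parent=FAD3B
CP027622.1	linumpool	exon	1035600	1035895	.	+	.	ID=FAD3B.e2;Parent=FAD3B
CP027622.1	linumpool	exon	1036400	1036545	.	+	.	ID=FAD3B.e3;Parent=FAD3B
CP027622.1	linumpool	exon	1036900	1037045	.	+	.	ID=FAD3B.e4;Parent=FAD3B
CP027622.1	linumpool	exon	1037400	1037545	.	+	.	ID=FAD3B.e5;Parent=FAD3B
CP027622.1	linumpool	exon	1038000	1038145	.	+	.	ID=FAD3B.e6;Parent=FAD3B
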