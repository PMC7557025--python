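gene	chromosome	position	location	ref_allele	alt_allele	fatty_acid	rs_varscan	p_varscan	rs_freebayes	p_freebayes	key_site
SAD1	CP027620.1	2257330	upstream	A	G	OLE	0.37	4e-4	0.37	5e-4	0
SAD1	CP027620.1	2257353	upstream	T	C	OLE	0.35	0.001	0.33	0.002	0
SAD1	CP027620.1	2258938	intron	C	G	OLE	0.27	0.01	0.34	0.002	0
SAD1	CP027620.1	2258980	intron	T	C	OLE	0.34	0.002	0.37	6e-4	0
SAD1	CP027620.1	2260202	downstream	T	G	OLE	0.35	0.001	0.32	0.003	0
SAD2	CP027621.1	17364707	upstream	A	AG	OLE	0.31	0.004	0.30	0.005	0
SAD2	CP027621.1	17365164	exon	T	C	STE	0.31	0.009	0.31	0.009	0
SAD2	CP027621.1	17367383	downstream	G	T	LIO	-0.28	0.01	-0.28	0.01	0
FAD2A	CP027619.1	5296364	exon	G	A	PAL	-0.28	0.01	-0.29	0.007	0
FAD2A	CP027619.1	5296364	exon	G	A	STE	-0.34	0.002	-0.34	0.002	0
FAD2A	CP027619.1	5296658	exon	C	T	STE	0.38	4e-4	0.39	3e-4	0
FAD2A	CP027619.1	5296705	downstream	C	A	PAL	0.35	0.006	0.35	0.005	0
FAD3A	CP027631.1	16092241	intron	T	C	LIN	-0.32	0.003	-0.35	0.001	0
FAD3A	CP027631.1	16092241	intron	T	C	PAL	0.29	0.008	0.28	0.009	0
FAD3A	CP027631.1	16092273	intron	C	A	LIN	-0.32	0.003	-0.37	4e-4	0
FAD3A	CP027631.1	16092294	exon	T	C	LIN	-0.33	0.002	-0.39	2e-4	0
FAD3A	CP027631.1	16092294	exon	T	C	LIO	0.32	0.003	0.34	0.002	0
FAD3A	CP027631.1	16092294	exon	T	C	PAL	0.36	7e-4	0.35	0.001	0
FAD3A	CP027631.1	16092348	exon	C	T	LIN	-0.29	0.008	-0.29	0.007	1
FAD3A	CP027631.1	16092348	exon	C	T	PAL	0.33	0.002	0.34	0.002	1
FAD3A	CP027631.1	16092575	exon	C	T	LIN	-0.36	8e-4	-0.42	7e-6	0
FAD3A	CP027631.1	16092674	upstream	G	T	LIN	-0.32	0.003	-0.38	3e-4	0
FAD3A	CP027631.1	16092741	upstream	T	TAA	LIN	-0.37	5e-4	-0.36	8e-4	0
FAD3A	CP027631.1	16093029	upstream	T	C	LIN	-0.36	8e-4	-0.42	9e-6	0
FAD3A	CP027631.1	16093029	upstream	T	C	LIO	0.27	0.01	0.28	0.01	0
FAD3A	CP027631.1	16093029	upstream	T	C	PAL	0.39	3e-4	0.40	2e-4	0
FAD3A	CP027631.1	16093040	upstream	C	A	LIN	-0.43	7e-6	-0.45	2e-6	0
FAD3A	CP027631.1	16093040	upstream	C	A	LIO	0.33	0.003	0.29	0.008	0
FAD3A	CP027631.1	16093040	upstream	C	A	PAL	0.35	0.001	0.33	0.002	0
FAD3B	CP027622.1	1034358	upstream	G	A	STE	0.28	0.01	0.26	0.02	0
FAD3B	CP027622.1	1034389	upstream	A	G	LIO	-0.31	0.005	-0.31	0.004	0
FAD3B	CP027622.1	1034526	upstream	C	A	LIO	-0.26	0.02	-0.25	0.02	0
FAD3B	CP027622.1	1034873	upstream	G	A	LIO	-0.32	0.004	-0.27	0.02	0
FAD3B	CP027622.1	1034904	upstream	G	C	LIO	-0.30	0.007	-0.30	0.006	0
FAD3B	CP027622.1	1035028	upstream	A	G	LIO	-0.28	0.01	-0.29	0.007	0
FAD3B	CP027622.1	1035480	exon	A	G	LIO	-0.29	0.007	-0.30	0.006	0
FAD3B	CP027622.1	1035655	exon	C	T	LIO	0.28	0.009	0.32	0.003	1
FAD3B	CP027622.1	1035655	exon	C	T	LIN	-0.37	6e-4	-0.38	4e-4	1
FAD3B	CP027622.1	1035655	exon	C	T	PAL	0.32	0.003	0.33	0.002	1
FAD3B	CP027622.1	1035674	exon	T	G	LIO	-0.26	0.02	-0.29	0.007	0
FAD3B	CP027622.1	1036195	intron	G	T	LIO	-0.26	0.02	-0.30	0.006	0
FAD3B	CP027622.1	1037964	intron	G	C	LIN	-0.26	0.02	-0.25	0.02	0
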