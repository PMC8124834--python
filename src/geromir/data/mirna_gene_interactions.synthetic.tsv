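mirna	gene	evidence
mmu-miR-10a	Cercam	Microarray
mmu-miR-26a	Cercam	Microarray
mmu-miR-26b	Cercam	Microarray
mmu-miR-15a	Spsb4	Microarray
mmu-miR-16	Spsb4	Microarray
mmu-miR-24	Spsb4	Microarray
mmu-miR-15a	Bcl2	Luciferase reporter assay//Western blot
mmu-miR-16	Bcl2	Luciferase reporter assay//Western blot
mmu-miR-15a	Ccnd1	Luciferase reporter assay
mmu-miR-16	Wnt3a	Luciferase reporter assay
mmu-miR-16	Mcl1	Western blot
mmu-miR-22	Hdac1	Luciferase reporter assay//qRT-PCR
mmu-miR-22	Sirt1	Western blot
mmu-miR-29a	Dnmt3a	Luciferase reporter assay
mmu-miR-29b	Dnmt3a	Luciferase reporter assay
mmu-miR-29c	Dnmt3b	Luciferase reporter assay
mmu-miR-29a	Loxl4	Microarray
mmu-miR-26b	Lef1	Luciferase reporter assay
mmu-miR-10a	Usf2	Western blot
mmu-miR-10a	Pik3ca	qRT-PCR
mmu-miR-146a	Traf6	Luciferase reporter assay//Western blot
mmu-miR-146a	Irak1	Luciferase reporter assay//Western blot
mmu-miR-155	Socs1	Luciferase reporter assay
mmu-miR-24	Aurkb	HITS-CLIP
mmu-miR-25	Bcl2l11	Luciferase reporter assay
mmu-miR-93	Pten	Luciferase reporter assay
mmu-miR-106b	Pten	Luciferase reporter assay
mmu-miR-20a	E2f1	Luciferase reporter assay
mmu-miR-19b	Pten	Western blot
mmu-miR-223	Nfix	HITS-CLIP
mmu-miR-126	Spred1	Luciferase reporter assay
mmu-miR-143	Kras	Luciferase reporter assay
mmu-miR-152	Dnmt1	Luciferase reporter assay
mmu-miR-103	Dicer1	Western blot
mmu-miR-18a	Esr1	Luciferase reporter assay
mmu-miR-34a	Sirt1	Luciferase reporter assay
mmu-miR-98	Igf1	Microarray
mmu-let-7b	Lin28a	Luciferase reporter assay
mmu-miR-21	Pten	Luciferase reporter assay
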