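hallmark	mirna	downregulated
altered DNA damage response	miR-106b	1
altered DNA damage response	miR-125b	0
altered DNA damage response	miR-138	0
altered DNA damage response	miR-182	0
altered DNA damage response	miR-18a	1
altered DNA damage response	miR-192	0
altered DNA damage response	miR-194	1
altered DNA damage response	miR-210	0
altered DNA damage response	miR-215	0
altered DNA damage response	miR-22	1
altered DNA damage response	miR-24	1
altered DNA damage response	miR-34a	0
altered DNA damage response	miR-34b	0
altered DNA damage response	miR-34c	0
altered DNA damage response	miR-421	0
altered DNA damage response	miR-504	0
loss of telomeres	miR-103	1
loss of telomeres	miR-124	0
loss of telomeres	miR-138	0
loss of telomeres	miR-143	1
loss of telomeres	miR-155	1
loss of telomeres	miR-34a	0
loss of telomeres	miR-34b	0
loss of telomeres	miR-34c	0
DNA methylation	miR-127	0
DNA methylation	miR-143	1
DNA methylation	miR-148a	0
DNA methylation	miR-152	1
DNA methylation	miR-29a	1
DNA methylation	miR-29b	1
DNA methylation	miR-29c	1
DNA methylation	miR-34a	0
DNA methylation	miR-34b	0
DNA methylation	miR-34c	0
DNA methylation	miR-9	0
histone modifications	miR-144	0
histone modifications	miR-15a	1
histone modifications	miR-16	1
histone modifications	miR-26a	1
histone modifications	miR-29a	1
histone modifications	miR-29b	1
histone modifications	miR-29c	1
histone modifications	miR-98	0
regulation of splicing	miR-10a	1
regulation of splicing	miR-10b	0
regulation of splicing	miR-125a	0
regulation of splicing	miR-137	0
regulation of splicing	miR-16	1
regulation of splicing	miR-340	0
changes to protein homeostasis	miR-106b	1
changes to protein homeostasis	miR-26b	1
changes to protein homeostasis	miR-301b	0
changes to protein homeostasis	miR-320	0
altered nutrient sensing	miR-106a	0
altered nutrient sensing	miR-126	1
altered nutrient sensing	miR-17	0
altered nutrient sensing	miR-182	0
altered nutrient sensing	miR-190b	0
altered nutrient sensing	miR-19b	1
altered nutrient sensing	miR-206	0
altered nutrient sensing	miR-20a	1
altered nutrient sensing	miR-223	1
altered nutrient sensing	miR-320	0
altered nutrient sensing	miR-470	0
altered nutrient sensing	miR-486	0
altered nutrient sensing	miR-669b	0
altered nutrient sensing	miR-681	0
mitochondrial dysfunction	let-7b	0
mitochondrial dysfunction	miR-106a	0
mitochondrial dysfunction	miR-133b	0
mitochondrial dysfunction	miR-146a	1
mitochondrial dysfunction	miR-181a	0
mitochondrial dysfunction	miR-19b	1
mitochondrial dysfunction	miR-20b	1
mitochondrial dysfunction	miR-221	0
mitochondrial dysfunction	miR-335	1
mitochondrial dysfunction	miR-34a	0
mitochondrial dysfunction	miR-34b	0
mitochondrial dysfunction	miR-34c	0
cellular senescence	let-7a	0
cellular senescence	miR-106a	0
cellular senescence	miR-17	0
cellular senescence	miR-181a	0
cellular senescence	miR-19b	1
cellular senescence	miR-20a	1
cellular senescence	miR-210	0
cellular senescence	miR-217	0
cellular senescence	miR-24	1
cellular senescence	miR-26b	1
cellular senescence	miR-29a	1
cellular senescence	miR-33	0
cellular senescence	miR-34a	0
cellular senescence	miR-34b	0
cellular senescence	miR-34c	0
cellular senescence	miR-499	0
stem cell exhaustion	let-7a	0
stem cell exhaustion	let-7b	0
stem cell exhaustion	miR-106b	1
stem cell exhaustion	miR-25	1
stem cell exhaustion	miR-290	0
stem cell exhaustion	miR-293	0
stem cell exhaustion	miR-294	0
stem cell exhaustion	miR-295	0
stem cell exhaustion	miR-29c	1
stem cell exhaustion	miR-33	0
stem cell exhaustion	miR-489	0
stem cell exhaustion	miR-499	0
stem cell exhaustion	miR-598	0
stem cell exhaustion	miR-93	1
inflammaging	miR-146a	1
inflammaging	miR-155	1
epigenetic alterations (Sirtuins)	miR-135a	0
epigenetic alterations (Sirtuins)	miR-199b	0
epigenetic alterations (Sirtuins)	miR-204	0
epigenetic alterations (Sirtuins)	miR-217	0
epigenetic alterations (Sirtuins)	miR-290	0
epigenetic alterations (Sirtuins)	miR-486	0
epigenetic alterations (Sirtuins)	miR-9	0
stem cell homeostasis	let-7b	0
stem cell homeostasis	miR-16	1
stem cell homeostasis	miR-33	0
stem cell homeostasis	miR-376b	0
stem cell homeostasis	miR-486	0
stem cell homeostasis	miR-489	0
stem cell homeostasis	miR-598	0
stem cell homeostasis	miR-9	0
insulin/IGF1	miR-206	0
insulin/IGF1	miR-320	0
insulin/IGF1	miR-470	0
insulin/IGF1	miR-669b	0
insulin/IGF1	miR-681	0
altered intercellular communication	miR-29a	1
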