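gene_label	reference_cpg	chrom	start	end	strand	expected_cpg_count
AHRR	cg05575921	chr5	372478	373819	+	44
ALPPL2	cg21566642	chr2	233283630	233284930	-	114
IER3	cg06126421	chr6	30719327	30720645	+	19
GNG12	cg25189904	chr1	68298855	68300158	-	85
GFI1	cg09935388	chr1	92947265	92948622	+	73
CACNA1D	cg15417641	chr3	53699512	53700811	-	17
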