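key	value
embryos_total	359
embryos_genomewide_abnormal_both_methods	5
embryos_underrepresented_haplotype	4
samples_screened_for_underrepresentation	354
embryos_in_chromosome_comparison	350
true_negatives	8234
false_negatives	0
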