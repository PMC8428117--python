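# SYNTHETIC stand-in qPCR raw-data sheet (not measured data).
# Replicate Ct values for a genomic copy-number comparison of a
# multi-copy Y-locus target gene vs a single-copy autosomal reference
# in mutant (test) vs wildtype (control) genomic DNA.
# Generated by pirnascan.simulate.make_ct_table with a true 3-fold
# copy-number reduction (fold 1/3), Gaussian Ct noise sd 0.2, n=6
# replicates, generator seed 0.
sample_group	replicate_id	gene_role	ct
control	r1	target	23.981049474175112
control	r1	reference	19.89807690722137
control	r2	target	24.06034391396229
control	r2	reference	19.474743634776864
control	r3	target	24.04211868930129
control	r3	reference	19.61537190862666
control	r4	target	23.71778028133901
control	r4	reference	19.979945537713995
control	r5	target	23.664234066802425
control	r5	reference	19.8654846568883
control	r6	target	23.86164250108341
control	r6	reference	19.813561460992982
test	r1	target	25.567257519768443
test	r1	reference	20.04922435987549
test	r2	target	25.91702269659252
test	r2	reference	20.32399272544951
test	r3	target	25.843993127106746
test	r3	reference	20.2387959287556
test	r4	target	25.600560409964256
test	r4	reference	19.675459795551813
test	r5	target	25.695440451801666
test	r5	reference	20.224058839144824
test	r6	target	25.36474573293685
test	r6	reference	20.166696082481863
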