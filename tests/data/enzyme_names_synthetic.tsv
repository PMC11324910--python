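name	ec
alpha amylase	3.2.1.1
oligo 1 6 glucosidase	3.2.1.10
dextranase	3.2.1.11
alpha glucosidase	3.2.1.20
amylo alpha 1 6 glucosidase	3.2.1.33
isoamylase	3.2.1.68
pullulan hydrolase	3.2.1.135
glycogen phosphorylase	2.4.1.1
4 alpha glucanotransferase	2.4.1.25
sucrose phosphorylase	2.4.1.7
levansucrase	2.4.1.10
beta fructofuranosidase	3.2.1.26
beta galactosidase	3.2.1.23
beta glucosidase	3.2.1.21
cellulase	3.2.1.4
chitinase	3.2.1.14
lysozyme	3.2.1.17
pullulanase	3.2.1.41
cyclomaltodextrin glucanotransferase	2.4.1.19
maltose phosphorylase	2.4.1.8
trehalose phosphorylase	2.4.1.64
alcohol dehydrogenase	1.1.1.1
lactate dehydrogenase	1.1.1.27
glyceraldehyde 3 phosphate dehydrogenase	1.2.1.12
pyruvate kinase	2.7.1.40
hexokinase	2.7.1.1
dna directed rna polymerase	2.7.7.6
methionine synthase	2.1.1.13
methylmalonyl coa mutase	5.4.99.2
succinate dehydrogenase	1.3.5.1
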