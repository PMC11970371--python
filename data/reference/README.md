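# Reference haplotypes (not distributed)

The paper-scale sensitivity and error-rate-robustness checks in
`tests/test_acceptance.py` need real phased reference haplotypes as the LD
backbone — synthetic cohorts reproduce the qualitative power trends but not
absolute sensitivities.

To run them, place one plain-text phased VCF per disease locus in this
directory (`<locus>.vcf`), e.g. 20-cM windows of 1000 Genomes Phase 3 EUR
haplotypes around loci of interest, uncompressed, biallelic records only.
Download and window the data yourself (it is not redistributed here); any
single-chromosome phased VCF readable by `haploscreen.io.read_phased_vcf`
works. Without these files the two tests fail with a message pointing here.
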