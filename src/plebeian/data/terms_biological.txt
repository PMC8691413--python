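# Biological Taxonomy: official virological nomenclature.
sars-cov-2
alpha variant
b.1.617
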