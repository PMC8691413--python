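# Keyword filter for likely-misinformative COVID-19 posts.
china virus
bioweapon
microchip
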