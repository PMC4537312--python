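# Homonym phrases where the term is not an ADE (psychiatric jargon)
ego dystonia
ego dystonic
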