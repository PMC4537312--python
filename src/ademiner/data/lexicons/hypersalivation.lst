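hypersalivation
sialorrhea
sialorrhoea
excessive salivation
drooling
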