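# Drug-literature / vaccine context: side effects of a drug being discussed
leaflet
information leaflet
vaccine
vaccination
associated with
listed effects of
datasheet
product information
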