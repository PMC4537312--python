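# Charity / research organisation words adjacent to an ADE term
society
workshop
association
foundation
charity
support group
network
conference
awareness week
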