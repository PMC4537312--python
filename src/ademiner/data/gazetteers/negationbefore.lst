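# Negation cues that precede an ADE term
not
no
never
nil
denied
denies
denying
without
no evidence of
no sign of
no signs of
no history of
free of
free from
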