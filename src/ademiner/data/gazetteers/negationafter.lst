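# Negation cues that follow an ADE term
ruled out
excluded
unlikely
absent
not present
not evident
not observed
not elicited
doubtful
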