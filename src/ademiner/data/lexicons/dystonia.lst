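# Dystonia: sustained muscle contraction, twisting, abnormal posture
dystonia
dystonias
dystonic
dystonic reaction
dystonic reactions
acute dystonia
oculogyric crisis
torticollis
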