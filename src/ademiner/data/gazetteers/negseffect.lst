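# Warning / information-giving about a potential side effect
side effect
side effects
adverse effect
adverse effects
risk of
risks of
can cause
may cause
could cause
might cause
warned about
warned of
warning about
possibility of
potential for
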