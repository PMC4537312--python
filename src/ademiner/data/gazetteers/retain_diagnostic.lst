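# Diagnostic phrases that are strong evidence of a real ADE
diagnosed with
diagnosis of
suffering from
suffers from
suffered from
presented with
presents with
presenting with
treated for
treatment for
complains of
complained of
experiencing
episode of
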