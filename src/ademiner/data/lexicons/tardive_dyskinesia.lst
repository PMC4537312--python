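# Tardive dyskinesia: slow repetitive movements after long-term use
tardive dyskinesia
tardive dyskinesias
dyskinesia
dyskinesias
dyskinetic
orofacial dyskinesia
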