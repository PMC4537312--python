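# Clinician is monitoring for the ADE, not recording it
check for
checked for
checking for
monitor for
monitoring for
monitored for
observe for
observed for
watch for
watching for
look out for
screen for
screening for
review for
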