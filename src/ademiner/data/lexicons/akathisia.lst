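# Akathisia: inner restlessness, inability to stay still
akathisia
akathisic
# curated alternate spellings seen in clinical text
acathisia
acasthisia
akithisia
akathesia
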