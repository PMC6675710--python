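cell,count
tp,524
fp,13
fn,233
tn,133
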