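{
 "chr6": [[700000, 900000, "q26"]],
 "chr8": [[2900000, 3100000, "q21.3"]]
}
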