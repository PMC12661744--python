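study,treatment,events,sample_size
s001,A,81,193
s001,B,104,236
s002,A,68,234
s002,B,78,195
s003,A,62,236
s003,C,57,233
s004,A,73,225
s004,C,69,218
s005,B,78,183
s005,C,53,172
s006,B,94,240
s006,C,57,179
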