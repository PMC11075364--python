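1 0.111111 0.111111 0.100000 0.116667
2 0.313889 0.111111 0.127778 0.083333
2 0.516667 0.111111 0.100000 0.100000
1 0.719444 0.111111 0.116667 0.083333
0 0.112500 0.315278 0.097222 0.125000
0 0.315278 0.315278 0.119444 0.113889
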