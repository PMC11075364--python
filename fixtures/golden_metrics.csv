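name,tp,fp,fn,precision,recall,f1
A,3.000000,1.000000,0.000000,75.000000,100.000000,85.714286
B,2.000000,0.000000,2.000000,100.000000,50.000000,66.666667
macro,,,,87.500000,75.000000,80.769231
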