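id,ic50_uM,split
I1,1.7,train
I2,6.1,train
I3,5.3,test
I4,2.6,test
I5,1.9,train
I6,2.5,train
I7,1.8,train
I8,2.7,train
I9,2.0,train
I10,2.5,train
I11,1.9,train
I12,4.6,train
I13,19,train
I14,4.2,test
I15,12,train
I16,17,train
I17,5.7,train
I18,4.7,train
I19,2.9,train
I20,3.0,test
I21,11,train
I22,6.0,train
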