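name,delta14c,sigma,n
DIC,-157.7,1.7,1
DOC,-231.0,1.7,1
SOC,-504.4,173.0,20
plant,-55.1,61.8,8
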