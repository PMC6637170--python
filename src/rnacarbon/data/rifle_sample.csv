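name,delta14c,sigma
LQ107_RNA,-193.4,5.6
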