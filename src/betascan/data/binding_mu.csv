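compound_id,receptor,ic50_nM,sem_nM,censored
1,mu,5.1,3.5,False
10,mu,1000,,True
12,mu,1.9,2.4,False
13,mu,338.8,5.1,False
14,mu,11.2,6.3,False
15,mu,954.9,2.9,False
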