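subject,act_ed,ecg_ed,pox_ed,act_es,ecg_es,pox_es
1,2.4,2.2,1.8,1.5,1.6,1.7
2,2.6,0.9,1.9,2.1,0.5,1.6
3,2.9,2.7,2.5,2.6,2.4,2.1
4,2.9,1.7,2.8,2.6,1.2,2.4
5,2.5,1.9,1.9,2.1,1.7,1.7
6,1.6,2.1,1.8,1.5,1.5,1.4
7,1.5,1.6,1.1,1.1,1.6,1.0
8,2.8,1.1,2.4,2.4,0.8,1.5
9,2.1,0.7,1.3,1.9,0.5,0.9
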