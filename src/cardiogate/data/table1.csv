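subject,act_interval_mean,ecg_interval_mean,pox_interval_mean,act_interval_sd,ecg_interval_sd,pox_interval_sd,act_offset_sd,ecg_offset_sd,pox_offset_sd
1,869,865,840,89,54,45,78,10,11
2,870,795,1103,83,126,87,76,477,101
3,875,845,834,48,28,34,13,3,19
4,1064,999,1079,76,143,52,44,456,456
5,926,990,923,49,54,31,14,56,23
6,841,939,898,95,69,35,149,52,15
7,848,839,876,79,62,48,75,257,67
8,1110,886,1091,37,174,33,1,1047,14
9,762,576,660,81,168,144,112,488,331
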