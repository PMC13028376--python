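frequency_hz,total_periods,ramp_periods,full_periods,period_ms,total_ms
16,16,3,10,62.5,1000
20,20,3,14,50,1000
40,30,4,22,25,750
63,38,4,30,15.9,604
80,48,4,40,12.5,600
125,75,4,67,8,600
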