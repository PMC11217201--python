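measurement_id,system,quantity,test_ml_min,retest_ml_min
150-20,DMI-20,Qin,40,37
150-20,Vision-600,Qin,49,37
150-20,DMI-20,Qout,38,37
150-20,Vision-600,Qout,62,46
150-40,DMI-20,Qin,72,72
150-40,Vision-600,Qin,81,79
150-40,DMI-20,Qout,63,64
150-40,Vision-600,Qout,90,89
150-60,DMI-20,Qin,111,111
150-60,Vision-600,Qin,112,99
150-60,DMI-20,Qout,106,107
150-60,Vision-600,Qout,122,111
150-80,DMI-20,Qin,146,145
150-80,Vision-600,Qin,140,134
150-80,DMI-20,Qout,138,140
150-80,Vision-600,Qout,153,148
200-20,DMI-20,Qin,49,50
200-20,Vision-600,Qin,48,47
200-20,DMI-20,Qout,43,47
200-20,Vision-600,Qout,55,54
200-40,DMI-20,Qin,99,99
200-40,Vision-600,Qin,112,94
200-40,DMI-20,Qout,94,93
200-40,Vision-600,Qout,127,106
200-60,DMI-20,Qin,159,156
200-60,Vision-600,Qin,139,135
200-60,DMI-20,Qout,156,154
200-60,Vision-600,Qout,162,155
200-80,DMI-20,Qin,188,181
200-80,Vision-600,Qin,186,164
200-80,DMI-20,Qout,187,185
200-80,Vision-600,Qout,208,177
250-20,DMI-20,Qin,69,68
250-20,Vision-600,Qin,61,55
250-20,DMI-20,Qout,64,62
250-20,Vision-600,Qout,76,60
250-40,DMI-20,Qin,118,121
250-40,Vision-600,Qin,120,118
250-40,DMI-20,Qout,118,118
250-40,Vision-600,Qout,134,135
250-60,DMI-20,Qin,182,197
250-60,Vision-600,Qin,193,181
250-60,DMI-20,Qout,181,205
250-60,Vision-600,Qout,224,214
250-80,DMI-20,Qin,179,179
250-80,Vision-600,Qin,231,172
250-80,DMI-20,Qout,176,174
250-80,Vision-600,Qout,270,188
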