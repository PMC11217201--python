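measurement_id,system,session,qpump_ml_min,constriction_fraction,qcyl_nominal_ml_min,qcyl_measured_ml_min,qtube_nominal_ml_min,qtube_measured_ml_min
150-20,DMI-20,test,150,0.2,30,31,120,124
150-20,DMI-20,retest,150,0.2,30,30,120,127
150-20,Vision-600,test,150,0.2,30,33,120,118
150-20,Vision-600,retest,150,0.2,30,30,120,119
150-40,DMI-20,test,150,0.4,60,61,90,98
150-40,DMI-20,retest,150,0.4,60,59,90,99
150-40,Vision-600,test,150,0.4,60,61,90,87
150-40,Vision-600,retest,150,0.4,60,61,90,81
150-60,DMI-20,test,150,0.6,90,91,60,63
150-60,DMI-20,retest,150,0.6,90,94,60,61
150-60,Vision-600,test,150,0.6,90,94,60,60
150-60,Vision-600,retest,150,0.6,90,85,60,58
150-80,DMI-20,test,150,0.8,120,119,30,32
150-80,DMI-20,retest,150,0.8,120,120,30,31
150-80,Vision-600,test,150,0.8,120,126,30,31
150-80,Vision-600,retest,150,0.8,120,125,30,26
200-20,DMI-20,test,200,0.2,40,41,160,171
200-20,DMI-20,retest,200,0.2,40,43,160,168
200-20,Vision-600,test,200,0.2,40,39,160,173
200-20,Vision-600,retest,200,0.2,40,42,160,158
200-40,DMI-20,test,200,0.4,80,80,120,132
200-40,DMI-20,retest,200,0.4,80,80,120,134
200-40,Vision-600,test,200,0.4,80,100,120,122
200-40,Vision-600,retest,200,0.4,80,81,120,119
200-60,DMI-20,test,200,0.6,120,126,80,83
200-60,DMI-20,retest,200,0.6,120,131,80,80
200-60,Vision-600,test,200,0.6,120,125,80,86
200-60,Vision-600,retest,200,0.6,120,122,80,84
200-80,DMI-20,test,200,0.8,160,163,40,41
200-80,DMI-20,retest,200,0.8,160,162,40,42
200-80,Vision-600,test,200,0.8,160,166,40,39
200-80,Vision-600,retest,200,0.8,160,164,40,31
250-20,DMI-20,test,250,0.2,50,49,200,200
250-20,DMI-20,retest,250,0.2,50,47,200,203
250-20,Vision-600,test,250,0.2,50,51,200,222
250-20,Vision-600,retest,250,0.2,50,50,200,211
250-40,DMI-20,test,250,0.4,100,102,150,162
250-40,DMI-20,retest,250,0.4,100,99,150,166
250-40,Vision-600,test,250,0.4,100,101,150,182
250-40,Vision-600,retest,250,0.4,100,100,150,163
250-60,DMI-20,test,250,0.6,150,153,100,103
250-60,DMI-20,retest,250,0.6,150,160,100,100
250-60,Vision-600,test,250,0.6,150,174,100,104
250-60,Vision-600,retest,250,0.6,150,146,100,114
250-80,DMI-20,test,250,0.8,200,200,50,52
250-80,DMI-20,retest,250,0.8,200,204,50,53
250-80,Vision-600,test,250,0.8,200,222,50,56
250-80,Vision-600,retest,250,0.8,200,218,50,43
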