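measurement_id,system,test_MBq,retest_MBq,printed_difference_percent,printed_decimals,inconsistent
150-20,DMI-20,496,479,-3.43,2,False
150-20,Vision-600,482,506,4.98,2,False
150-40,DMI-20,478,487,1.88,2,False
150-40,Vision-600,476,507,6.51,2,False
150-60,DMI-20,482,448,-7.05,2,False
150-60,Vision-600,513,509,-0.78,2,False
150-80,DMI-20,444,431,-2.93,2,False
150-80,Vision-600,517,530,2.51,2,False
200-20,DMI-20,474,450,-5.06,2,False
200-20,Vision-600,548,529,-3.47,2,False
200-40,DMI-20,459,441,-3.92,2,False
200-40,Vision-600,510,513,0.59,2,False
200-60,DMI-20,507,480,-5.33,2,False
200-60,Vision-600,521,536,2.88,2,False
200-80,DMI-20,514,497,-3.31,2,False
200-80,Vision-600,527,527,0.00,2,False
250-20,DMI-20,483,486,0.62,2,False
250-20,Vision-600,543,506,-6.8,1,False
250-40,DMI-20,515,472,-8.35,2,False
250-40,Vision-600,539,544,0.9,1,False
250-60,DMI-20,492,510,3.66,2,False
250-60,Vision-600,556,520,-6.47,2,False
250-80,DMI-20,511,483,-5.48,2,False
250-80,Vision-600,529,532,0.57,2,False
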