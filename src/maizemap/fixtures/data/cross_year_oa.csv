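train_year,test_year,overall_accuracy
2017,2018,0.79
2017,2019,0.86
2018,2017,0.89
2018,2019,0.90
2019,2017,0.82
2019,2018,0.81
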