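compound,plc50_exp,plc50_pred,residual_printed,role,residual_consistent,act_matches_table1
4a,4.017,3.936,-0.081,test,yes,yes
4b,4.623,4.562,-0.061,train,yes,yes
4c,5.026,5.032,0.006,train,yes,yes
4d,5.119,5.161,0.042,train,yes,yes
4e,4.137,4.121,-0.016,train,yes,yes
4f,4.024,4.022,-0.002,train,yes,yes
4g,3.854,3.885,0.031,train,yes,yes
4h,4.937,4.920,-0.017,train,yes,yes
4i,4.735,4.791,0.056,test,yes,yes
4j,4.017,4.005,-0.012,train,yes,no
4k,4.211,4.222,0.011,train,yes,yes
4l,4.085,4.089,0.004,test,yes,yes
5a,4.395,4.432,0.037,train,yes,yes
5b,4.227,4.206,-0.021,test,yes,yes
5c,4.056,4.128,0.072,train,yes,yes
5d,4.768,4.794,0.026,train,yes,yes
5e,4.117,4.104,-0.013,train,yes,no
5f,3.788,3.852,0.064,train,yes,yes
5g,4.380,4.397,-0.059,test,no,yes
5h,4.267,4.287,0.020,train,yes,yes
5i,4.228,4.225,-0.003,train,yes,yes
5j,4.217,4.170,-0.047,train,yes,yes
5k,4.070,4.017,-0.053,train,yes,yes
5l,4.561,4.527,-0.034,train,yes,yes
6a,4.004,4.005,0.001,train,yes,yes
6b,4.294,4.260,-0.034,train,yes,yes
6c,4.406,4.393,-0.013,train,yes,yes
6d,4.312,4.305,-0.007,train,yes,yes
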