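m,n,exact,estimated,error,abs_error,ape
3,1,215.519,215.515,-0.004,0.004,0.0018
3,2,427.787,427.780,-0.007,0.007,0.0016
3,3,640.066,640.054,-0.012,0.012,0.0018
3,4,852.338,852.341,-0.002,0.002,0.0002
3,5,1064.611,1064.634,-0.023,0.023,0.0021
3,6,1276.885,1276.940,-0.055,0.055,0.0043
3,7,1489.158,1489.256,0.098,0.098,0.0066
3,8,1701.432,1701.583,0.151,0.151,0.0089
3,9,1919.705,1913.920,0.215,0.215,0.0112
3,10,2125.979,2126.267,0.288,0.288,0.013
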