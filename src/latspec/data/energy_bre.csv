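m,n,exact,estimated,error,abs_error,ape
3,1,109.376,109.378,0.0014,0.0014,0.0013
3,2,215.887,215.890,0.0036,0.0036,0.0017
3,3,322.361,322.360,-0.0010,0.0010,0.0003
3,4,428.834,428.825,-0.0087,0.0087,0.0020
3,5,535.305,535.170,-0.1347,0.1347,0.0252
3,6,641.779,641.651,-0.2677,0.2677,0.0417
3,7,748.264,748.809,-0.4554,0.4554,0.0609
3,8,854.742,854.063,-0.6790,0.6790,0.0794
3,9,961.220,961.275,-0.9456,0.9456,0.0983
3,10,1067.699,1067.444,1.2551,1.2551,0.1175
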