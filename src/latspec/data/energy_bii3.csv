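m,n,exact,estimated,error,abs_error,ape
3,1,66.950,66.966,0.016,0.016,0.023
3,2,116.924,116.989,0.065,0.065,0.056
3,3,167.849,167.919,0.070,0.070,0.041
3,4,218.775,218.849,0.074,0.074,0.033
3,5,269.701,269.779,0.078,0.078,0.029
3,6,320.626,320.709,0.082,0.082,0.026
3,7,371.552,371.640,0.088,0.088,0.024
3,8,422.478,422.570,0.091,0.091,0.022
3,9,473.403,473.500,0.097,0.097,0.020
3,10,524.328,524.431,0.102,0.102,0.019
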