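solvent_id,alpha,beta,pi_star,delta_H
water,1.17,0.47,1.09,47.8
methanol,0.98,0.66,0.60,29.6
ethanol,0.86,0.75,0.54,26.5
1-propanol,0.84,0.90,0.52,24.5
2-propanol,0.76,0.84,0.48,23.5
1-butanol,0.84,0.84,0.47,23.2
2-butanol,0.69,0.80,0.40,22.2
acetonitrile,0.19,0.40,0.75,24.3
acetone,0.08,0.43,0.71,19.9
ethyl acetate,0.00,0.45,0.55,18.2
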