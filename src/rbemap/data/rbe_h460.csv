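ion,column,y_d_kev_um,rbe_sf05,rbe_sf01
helium,1,10.4,1.24,
helium,2,13.8,1.34,1.58
helium,3,19.1,1.37,1.75
helium,4,27.9,1.36,1.70
helium,5,42.0,1.54,1.88
helium,6,51.4,2.03,2.26
helium,7,62.0,2.74,2.70
helium,8,70.8,3.12,3.47
helium,9,79.0,4.06,4.13
helium,10,84.9,3.89,4.25
helium,11,88.0,4.10,3.62
helium,12,84.7,2.97,
carbon,1,18.6,1.51,1.60
carbon,2,36.2,2.31,2.29
carbon,3,55.6,4.02,3.55
carbon,4,61.3,3.99,3.55
carbon,5,72.6,4.57,4.15
carbon,6,87.9,5.24,4.28
carbon,7,113.8,4.51,3.96
carbon,8,146.0,4.59,3.65
carbon,9,181.3,3.61,3.05
carbon,10,230.8,3.16,2.49
carbon,11,263.6,2.06,1.60
carbon,12,270.3,0.68,
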