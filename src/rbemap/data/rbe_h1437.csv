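ion,column,y_d_kev_um,rbe_sf05,rbe_sf01
helium,1,10.4,,
helium,2,13.8,0.61,
helium,3,19.1,1.00,
helium,4,27.9,1.61,0.96
helium,5,42.0,1.93,1.43
helium,6,51.4,2.60,1.81
helium,7,62.0,2.89,2.24
helium,8,70.8,4.41,2.91
helium,9,79.0,5.44,3.19
helium,10,84.9,3.97,2.33
helium,11,88.0,1.76,
helium,12,84.7,,
carbon,1,18.6,1.61,
carbon,2,36.2,2.22,1.79
carbon,3,55.6,3.50,2.46
carbon,4,61.3,3.82,2.26
carbon,5,72.6,4.31,2.53
carbon,6,87.9,4.81,2.82
carbon,7,113.8,4.56,2.67
carbon,8,146.0,4.31,2.52
carbon,9,181.3,3.76,2.21
carbon,10,230.8,3.40,1.99
carbon,11,263.6,2.12,1.24
carbon,12,270.3,0.95,
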