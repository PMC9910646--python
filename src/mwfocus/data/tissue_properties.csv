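material,frequency_hz,eps_r,sigma_s_per_m
Brain,1e8,89.8,0.79
Brain,1e9,48.9,1.31
Brain,1e10,34.6,9.78
Skull,1e8,27.6,0.173
Skull,1e9,20.6,0.364
Skull,1e10,12.7,3.86
Muscle,1e8,66,0.708
Muscle,1e9,54.8,0.978
Muscle,1e10,42.8,10.6
Blood,1e8,76.8,1.23
Blood,1e9,61.1,1.58
Blood,1e10,45.1,13.1
Fat,1e8,12.7,0.0684
Fat,1e9,11.3,0.116
Fat,1e10,8.8,1.71
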