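compound,conc_uM,mean_pct,sem_pct,n
Yakuchinone A,1,97.4,2.6,3
Yakuchinone A,10,119.6,4.4,3
6-paradol,1,103.9,4.5,3
6-paradol,10,131.3,6.2,3
6-shogaol,1,95.7,1.2,3
6-shogaol,10,106.37,3.2,3
8-shogaol,1,103.8,5.0,3
8-shogaol,10,117.8,4.6,3
6-gingerol,1,99.1,3.5,3
6-gingerol,10,103.6,2.0,3
8-gingerol,1,100.9,1.7,3
8-gingerol,10,117.56,1.6,3
Oxyphyllacinol,1,99.8,1.8,3
Oxyphyllacinol,10,120.4,3.6,3
Alpinoid D,1,101.2,4.6,3
Alpinoid D,10,126.5,2.7,3
Capsaicin,1,96.3,2.7,3
Capsaicin,10,97.4,1.9,3
Nonivamide,1,96.7,5.3,3
Nonivamide,10,94.2,2.6,3
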