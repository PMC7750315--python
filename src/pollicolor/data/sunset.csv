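wl,irradiance
300,5.139099e-04
310,8.369237e-04
320,1.316727e-03
330,2.007857e-03
340,2.976064e-03
350,4.298587e-03
360,6.063995e-03
370,8.371634e-03
380,1.133065e-02
390,1.505866e-02
400,1.968011e-02
410,2.532440e-02
420,3.212381e-02
430,4.021137e-02
440,4.971870e-02
450,6.077386e-02
460,7.349935e-02
470,8.801024e-02
480,1.044125e-01
490,1.228016e-01
500,1.432612e-01
510,1.658623e-01
520,1.906624e-01
530,2.177051e-01
540,2.470200e-01
550,2.786223e-01
560,3.125136e-01
570,3.486815e-01
580,3.871006e-01
590,4.277333e-01
600,4.705298e-01
610,5.154298e-01
620,5.623627e-01
630,6.112489e-01
640,6.620008e-01
650,7.145235e-01
660,7.687160e-01
670,8.244720e-01
680,8.816810e-01
690,9.402292e-01
700,1.000000e+00
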