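county,element,lcr_ingestion,lcr_dermal,lcr_inhalation,tlcr_published
Harris,As,8.59e-5,2.01e-6,5.41e-10,8.79e-5
Harris,Cd,4.42e-4,1.03e-5,2.78e-9,4.52e-4
Harris,Cr,1.67e-4,3.91e-6,1.05e-9,1.71e-4
Harris,Ni,1.61e-4,3.77e-6,1.02e-9,1.65e-4
Brazoria,As,3.58e-5,8.37e-7,2.26e-10,3.67e-5
Brazoria,Cd,2.03e-4,4.74e-6,1.28e-9,2.08e-4
Brazoria,Cr,1.33e-4,3.12e-6,8.41e-10,1.37e-4
Brazoria,Ni,1.30e-4,3.04e-6,8.21e-10,1.33e-4
Fort Bend,As,2.56e-5,5.97e-7,1.61e-10,2.62e-5
Fort Bend,Cd,3.13e-4,7.31e-6,1.97e-9,3.20e-4
Fort Bend,Cr,1.12e-4,2.61e-6,7.05e-10,1.15e-4
Fort Bend,Ni,9.30e-5,2.17e-6,5.86e-10,9.52e-5
Montgomery,As,8.77e-5,2.05e-6,5.53e-10,8.97e-5
Montgomery,Cd,1.18e-4,2.76e-6,7.45e-10,1.21e-4
Montgomery,Cr,1.58e-4,3.68e-6,9.93e-10,1.61e-4
Montgomery,Ni,1.98e-4,4.62e-6,1.25e-9,2.02e-4
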