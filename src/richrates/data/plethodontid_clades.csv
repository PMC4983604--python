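clade,ln_richness,n_sampled_morph,n_sampled_climate,crown_age,climate_rate,size_rate,shape_rate,gamma
Bolitoglossa_Eladinea,3.828641397,15,12,16.3,0.371,0.02225,0.00072,-2.69
Bolitoglossa_Magnadigitata,3.218875825,19,20,19.4,0.163,0.02981,0.00079,-2.65
Bolitoglossa_Bolitoglossa,2.833213344,10,10,18.8,0.169,0.01832,0.00083,-1.83
Pseudoeurycea_clade,3.931825633,32,37,27.6,0.205,0.05166,0.00231,-2.03
Chiropterotriton,2.48490665,7,7,16.6,0.039,0.0489,0.00043,-2.47
Oedipina,3.218875825,10,13,18.0,0.178,0.02155,0.00157,-1.74
Nototriton,2.564949358,5,6,13.5,0.080,0.01509,0.00172,-0.37
Gyrinophilus_clade,1.945910149,4,4,23.4,0.024,0.01565,0.00036,-2.17
Eurycea,3.583518939,17,24,22.7,0.047,0.09287,0.00205,-0.92
Plethodon_western,2.197224577,6,7,30.5,0.098,0.00423,0.00027,-1.40
Plethodon_cinereus_group,2.302585093,7,9,18.1,0.025,0.00615,0.00061,-1.53
Plethodon_wehrlei_welleri_group,1.945910149,6,7,19.9,0.029,0.01385,0.00025,-0.99
Plethodon_glutinosus_group,3.33220451,18,28,15.7,0.066,0.01679,0.00062,-2.48
Aneides,1.791759469,5,5,30.4,0.076,0.01056,0.00027,-1.37
Desmognathus_Phaeognathus,3.610917913,17,28,36.9,0.079,0.03865,0.00072,-1.90
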