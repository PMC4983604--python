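tip_label,display_name
Bolitoglossa_Eladinea,Subgenus Eladinea (Bolitoglossa)
Bolitoglossa_Magnadigitata,"Subgenera Magnadigitata, Oaxakia, Pachymandra (Bolitoglossa)"
Bolitoglossa_Bolitoglossa,"Subgenera Bolitoglossa, Mayamandra, Nanotriton (Bolitoglossa)"
Pseudoeurycea_clade,"Ixalotriton, Lineatriton, Parvimolge, Pseudoeurycea"
Chiropterotriton,Chiropterotriton
Oedipina,Oedipina
Nototriton,Nototriton
Gyrinophilus_clade,"Gyrinophilus, Pseudotriton, Stereochilus"
Eurycea,Eurycea
Plethodon_western,Western Plethodon
Plethodon_cinereus_group,Plethodon cinereus group
Plethodon_wehrlei_welleri_group,Plethodon wehrlei-welleri group
Plethodon_glutinosus_group,Plethodon glutinosus group
Aneides,Aneides
Desmognathus_Phaeognathus,"Desmognathus, Phaeognathus"
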