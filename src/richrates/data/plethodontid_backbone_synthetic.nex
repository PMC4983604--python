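#NEXUS
[ SYNTHETIC stand-in backbone phylogeny for the 15 plethodontid clades.    ]
[ Topology follows published plethodontid relationships (two subfamilies;  ]
[ Spelerpinae + tropical bolitoglossines within Hemidactyliinae; eastern   ]
[ vs. western Plethodon; Aneides with Desmognathus + Phaeognathus).        ]
[ Node ages (My) are plausible inventions with a 61-My root; they are NOT  ]
[ the ages of any published supplementary tree, so analyses run on this    ]
[ tree exercise the machinery but do not replicate published estimates.    ]

BEGIN TAXA;
    DIMENSIONS NTAX=15;
    TAXLABELS
        Aneides
        Desmognathus_Phaeognathus
        Plethodon_western
        Plethodon_wehrlei_welleri_group
        Plethodon_cinereus_group
        Plethodon_glutinosus_group
        Eurycea
        Gyrinophilus_clade
        Chiropterotriton
        Pseudoeurycea_clade
        Nototriton
        Oedipina
        Bolitoglossa_Eladinea
        Bolitoglossa_Magnadigitata
        Bolitoglossa_Bolitoglossa
    ;
END;

BEGIN TREES;
    TRANSLATE
        1 Aneides,
        2 Desmognathus_Phaeognathus,
        3 Plethodon_western,
        4 Plethodon_wehrlei_welleri_group,
        5 Plethodon_cinereus_group,
        6 Plethodon_glutinosus_group,
        7 Eurycea,
        8 Gyrinophilus_clade,
        9 Chiropterotriton,
        10 Pseudoeurycea_clade,
        11 Nototriton,
        12 Oedipina,
        13 Bolitoglossa_Eladinea,
        14 Bolitoglossa_Magnadigitata,
        15 Bolitoglossa_Bolitoglossa
    ;
    TREE backbone = (((1:41,2:41):4,(3:38,(4:30,(5:26,6:26):4):8):7):16,((7:40,8:40):10,(9:44,(10:40,((11:30,12:30):6,(13:28,(14:22,15:22):6):8):4):4):6):11);
END;
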