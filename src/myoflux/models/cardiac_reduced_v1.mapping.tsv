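reaction_id	protein_id
glut	Slc2a4
glut	Slc2a1
glyc	Hk2
glyc	Pfkm
glyc	Gapdh
glyc	Pkm
lacx	Slc16a1
lacx	Ldha
lacx	Ldhb
fat	Cd36
fat	Acsl1
box	Cpt1b
box	Cpt2
box	Acadvl
box	Hadha
box	Hadhb
ket_bhb	Bdh1
ket_bhb	Oxct1
ket_bhb	Acat1
ket_acac	Oxct1
ket_acac	Acat1
bcaa_val	Bcat2
bcaa_val	Bckdha
bcaa_val	Bckdhb
bcaa_val	Dbt
bcaa_leu	Bcat2
bcaa_leu	Bckdha
bcaa_leu	Bckdhb
bcaa_leu	Dbt
bcaa_ile	Bcat2
bcaa_ile	Bckdha
bcaa_ile	Bckdhb
bcaa_ile	Dbt
pdh	Pdha1
pdh	Pdhb
pdh	Dlat
tca	Cs
tca	Idh3a
tca	Ogdh
tca	Sdha
tca	Mdh2
tca	Fh1
tca	Sucla2
oxphos	Ndufs1
oxphos	Ndufv1
oxphos	Sdhb
oxphos	Uqcrc1
oxphos	Uqcrc2
oxphos	Cox4i1
oxphos	Atp5f1a
oxphos	Atp5f1b
oxphos	Slc25a4
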