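Alzheimer	Alzheimer's disease related genes	AR	ApoE	App	Bace	Casp3	Casp7	Esr1	Esr2	Ide	Il1r1	Mme	Psen	RARa	RARb	RARg	Tnfrsf1a
Autism	Autism related genes	AR	Cntnap2	En2	Esr1	Esr2	Fmr1	Foxp2	Gabrb3	Mecp2	Nlgn3	RARa	RARb	RARg	Reln	Slc6a4	Tsc1	Tsc2	Ube3a
Parkinson	Parkinson's disease related genes	AR	Casp3	Casp7	Casp9	Esr1	Esr2	Park2	Park7	RARa	RARb	RARg	Slc6a3	Snca	Th	Uchl1
Axon_guidance	Axon guidance related genes	1500003O03Rik	Abl1	Ablim1	Cfl1	Cxcl12	Efna4	Epha2	Ephb1	Nfatc2	Nfatc3	Ntng1	Sema3a	Sema3b	Sema3d	Sema3f	Sema3g	Sema6a	Sema6b	Sema6d	Srgap3	Unc5d
Pluripotent	Pluripotency related genes	Arid3b	Esrrb	Fkbp3	Hdac2	Klf4	Mybbp1a	Nacc1	Nanog	Nfkbib	Nr0b1	Nr5a2	Pou5f1	Rex1	Sall4	Smarcad1	Smarcc1	Sox2	Sp1	Spag1	Trim28	Zfp281	c-Myc
Neural_development	Neural development related genes	Atbf1	Cdyl	Fos	Gbx2	Gfap	Hras1	Map2	Mapk1	Mapk3	Nestin	Pla2g6	Raf1	Rhog	Rif1	Rps6ka1	Sall1	Shc1	Smarcad1	Sox2	Tuj1	Map2k1
Oxidative_stress	Oxidative stress related genes	Aass	Als2	Apoe	Ctsb	Dnm2	Fancc	Gpx7	Gpx8	Gusb	Hprt1	Kif9	Noxo1	Nxn	Park7	Ppp1r15b	Prdx2	Prdx6-rs1	Psmb5	Recql4	Scd1	Slc41a3	Sod1	Sod3	Txnip	Txnrd1	Xpa
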