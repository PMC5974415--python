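gene_symbol	gene_name	aliases	plane	experiment_id
Spn	Sialophorin	A630014B01Rik;Ly-48;Galgp;Cd43;Ly48	Sagittal	72002080
Qprt	Quinolinate phosphoribosyltransferase	AI647766;QPRTase;2410027J01Rik	Sagittal	71617020
Kif22	Kinesin family member 22	AU021460;Kid;C81217;Kif22a	Sagittal	72726
Maz	MYC-associated zinc finger protein (purine-binding transcription factor)	Pur-1;PUR1;SAF-1;SAF-2	Sagittal	71488768
Prrt2	Proline-rich transmembrane protein 2			
Pagr1a	RIKEN cDNA 2900092E17 gene	2900092E17Rik	Sagittal	68076546
Mvp	Major vault protein	LRP;VAULT1;2310009M24Rik	Sagittal	275693
Cdipt	CDP-diacylglycerol--inositol 3-phosphatidyltransferase (phosphatidylinositol synthase)	D7Bwg0575e;9530042F15Rik;Pis;Pis1	Sagittal	76098296
Sez6l2	Seizure-related 6 homolog like 2	AI835913;MGC19060;AW121566;Psk1;BSRP-A;MGC90604	Sagittal	1408
Asphd1	Aspartate beta-hydroxylase domain containing 1	MGC130534;Gm168;A830007L07Rik	Sagittal	69449026
Kctd13	Potassium channel tetramerization domain containing 13	Poldip1;PDIP1alpha;1500003N18Rik;AV259508	Sagittal	71488716
Tmem219	Transmembrane protein 219	2700081K05Rik;6330540D07Rik;mCG18160.2;CXorf44-like;LOC382245	Sagittal	70596194
Taok2	TAO kinase 2	MAP3K17;TAO1;KIAA0881;1110033K02Rik;TAO2;PSK1;mKIAA0881;PSK;B230344N16	Sagittal	72081744
Hirip3	HIRA interacting protein 3	B130036O03;C86302	Sagittal	69837911
Ino80e	INO80 complex subunit E	Ccdc85;MGC31515;AI225782;AI854876;Ccdc95	Sagittal	67815968
Doc2a	Double C2, alpha		Sagittal	68861994
Fam57b	Family with sequence similarity 57, member B	AI413816;MGC103222;AW060769;A330104J06Rik;1500016O10Rik	Sagittal	75831762
AldoA	Aldolase A, fructose-bisphosphate	Aldo-1;Aldo1;MGC107164	Sagittal	77620804
Ppp4c	Protein phosphatase 4, catalytic subunit	AU016079;Ppx;1110002D08Rik	Sagittal	632486
Tbx6	T-box 6	rv	Sagittal	71280631
Ypel3	Yippee-like 3 (Drosophila)	0610043B10Rik;1190001G19Rik;Suap	Sagittal	75214942
Mapk3	Mitogen-activated protein kinase 3	Prkm3;Esrk1;p44;Erk-1;Erk1;p44erk1;p44mapk;Mnk1;Mtap2k;Ert2	Sagittal	71608206
Coro1a	Coronin, actin-binding protein 1A	Clabp;p57;TACO;Lmb3	Sagittal	67978734
4930451I11Rik	RIKEN cDNA 4930451I11 gene		Sagittal	75851059
Zg16	Zymogen granule protein 16		Sagittal	68632924
AI467606	Expressed sequence AI467606		Sagittal	71656675
Gdpd3	Glycerophosphodiester phosphodiesterase domain containing 3	1110015E22Rik	Sagittal	75694405
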