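name	hmdb_id	formula	monoisotopic_mass	level	pathways	synonyms
Ascorbic acid	HMDB0000044	C6H8O6	176.03209	2	Ascorbate and aldarate metabolism	
Cyclic AMP	HMDB0000058	C10H12N5O6P	329.05252	2	Purine metabolism	
Creatine	HMDB0000064	C4H9N3O2	131.06948	2	Glycine, serine and threonine metabolism;Arginine and proline metabolism	
Pipecolic acid	HMDB0000070	C6H11NO2	129.07898	2	Lysine degradation	
Glycine	HMDB0000123	C2H5NO2	75.03203	1	Aminoacyl-tRNA biosynthesis;Glutathione metabolism;Glycine, serine and threonine metabolism;Nitrogen metabolism;Primary bile acid biosynthesis	
Guanine	HMDB0000132	C5H5N5O	151.04941	1	Purine metabolism	
Glycocholic acid	HMDB0000138	C26H43NO6	465.30904	1	Primary bile acid biosynthesis	
Hypoxanthine	HMDB0000157	C5H4N4O	136.03851	2	Purine metabolism	
L-Tyrosine	HMDB0000158	C9H11NO3	181.07389	1	Aminoacyl-tRNA biosynthesis;Phenylalanine, tyrosine and tryptophan biosynthesis;Tyrosine metabolism;Phenylalanine metabolism	tyrosine
L-Phenylalanine	HMDB0000159	C9H11NO2	165.07898	1	Aminoacyl-tRNA biosynthesis;Phenylalanine, tyrosine and tryptophan biosynthesis;Phenylalanine metabolism	phenylalanine
L-Alanine	HMDB0000161	C3H7NO2	89.04768	2	Aminoacyl-tRNA biosynthesis;Alanine, aspartate and glutamate metabolism	alanine
L-Proline	HMDB0000162	C5H9NO2	115.06333	2	Aminoacyl-tRNA biosynthesis;Arginine and proline metabolism	proline
L-Asparagine	HMDB0000168	C4H8N2O3	132.05349	1	Aminoacyl-tRNA biosynthesis;Alanine, aspartate and glutamate metabolism;Nitrogen metabolism	asparagine
L-Histidine	HMDB0000177	C6H9N3O2	155.06948	1	Aminoacyl-tRNA biosynthesis;Histidine metabolism	histidine
L-Lysine	HMDB0000182	C6H14N2O2	146.10553	1	Aminoacyl-tRNA biosynthesis;Lysine degradation	lysine
L-Serine	HMDB0000187	C3H7NO3	105.04259	1	Aminoacyl-tRNA biosynthesis;Glycine, serine and threonine metabolism;Cysteine and methionine metabolism	serine
L-Cystine	HMDB0000192	C6H12N2O4S2	240.02385	1	Cysteine and methionine metabolism;Glutathione metabolism	cystine
Phenylpyruvic acid	HMDB0000205	C9H8O3	164.04734	2	Phenylalanine metabolism;Phenylalanine, tyrosine and tryptophan biosynthesis	
N6-Acetyl-L-lysine	HMDB0000206	C8H16N2O3	188.11609	1	Lysine degradation	
Ornithine	HMDB0000214	C5H12N2O2	132.08988	1	Arginine and proline metabolism;Glutathione metabolism;Arginine biosynthesis	L-ornithine
Nicotinamide ribotide	HMDB0000229	C11H15N2O8P	334.05660	2	Nicotinate and nicotinamide metabolism	
Taurine	HMDB0000251	C2H7NO3S	125.01466	1	Taurine and hypotaurine metabolism;Primary bile acid biosynthesis	
Serotonin	HMDB0000259	C10H12N2O	176.09496	1	Tryptophan metabolism	
Sarcosine	HMDB0000271	C3H7NO2	89.04768	1	Glycine, serine and threonine metabolism	
Xanthosine	HMDB0000299	C10H12N4O6	284.07568	2	Purine metabolism	
Tryptamine	HMDB0000303	C10H12N2	160.10005	1	Tryptophan metabolism	
Tyramine	HMDB0000306	C8H11NO	137.08406	1	Tyrosine metabolism	
Aminoadipic acid	HMDB0000510	C6H11NO4	161.06881	2	Lysine degradation	2-aminoadipic acid
3-Methylglutarylcarnitine	HMDB0000552	C13H23NO6	289.15254	2		
L-Cysteine	HMDB0000574	C3H7NO2S	121.01975	1	Aminoacyl-tRNA biosynthesis;Cysteine and methionine metabolism;Glutathione metabolism;Taurine and hypotaurine metabolism	cysteine
Erythronic acid	HMDB0000613	C4H8O5	136.03717	2		
L-Homocystine	HMDB0000676	C8H16N2O4S2	268.05515	2	Cysteine and methionine metabolism	homocystine
Harderoporphyrin	HMDB0000683	C35H36N4O6	608.26348	2	Porphyrin metabolism	
L-Kynurenine	HMDB0000684	C10H12N2O3	208.08479	1	Tryptophan metabolism	kynurenine
L-Leucine	HMDB0000687	C6H13NO2	131.09463	1	Aminoacyl-tRNA biosynthesis;Valine, leucine and isoleucine biosynthesis	leucine
Isovalerylcarnitine	HMDB0000688	C12H23NO4	245.16271	2		
L-Methionine	HMDB0000696	C5H11NO2S	149.05105	1	Aminoacyl-tRNA biosynthesis;Cysteine and methionine metabolism	methionine
Kynurenic acid	HMDB0000715	C10H7NO3	189.04259	1	Tryptophan metabolism	
Hydroxyproline	HMDB0000725	C5H9NO3	131.05824	1	Arginine and proline metabolism	4-hydroxyproline
Indoleacrylic acid	HMDB0000734	C11H9NO2	187.06333	2	Tryptophan metabolism	
5-Hydroxyindoleacetic acid	HMDB0000763	C10H9NO3	191.05824	2	Tryptophan metabolism	5-HIAA
Oxypurinol	HMDB0000786	C5H4N4O2	152.03343	2	Purine metabolism	
Xanthurenic acid	HMDB0000881	C10H7NO4	205.03751	1	Tryptophan metabolism	
L-Valine	HMDB0000883	C5H11NO2	117.07898	1	Aminoacyl-tRNA biosynthesis;Valine, leucine and isoleucine biosynthesis	valine
Citrulline	HMDB0000904	C6H13N3O3	175.09569	1	Arginine and proline metabolism;Arginine biosynthesis	L-citrulline
Succinyladenosine	HMDB0000912	C14H17N5O8	383.10771	2	Purine metabolism	
Valerylglycine	HMDB0000927	C7H13NO3	159.08954	2		
L-Tryptophan	HMDB0000929	C11H12N2O2	204.08988	1	Aminoacyl-tRNA biosynthesis;Phenylalanine, tyrosine and tryptophan biosynthesis;Tryptophan metabolism	tryptophan
S-Adenosylhomocysteine	HMDB0000939	C14H20N4O5S	356.11544	2	Cysteine and methionine metabolism	
N-Acetylaspartylglutamic acid	HMDB0001067	C11H16N2O8	304.09067	2	Alanine, aspartate and glutamate metabolism	
6,8-Dihydroxypurine	HMDB0001182	C5H4N4O2	152.03343	2	Purine metabolism	
N-Acetylserotonin	HMDB0001238	C12H14N2O2	218.10553	2	Tryptophan metabolism	
N-Acetylarylamine	HMDB0001250	C8H9NO	135.06841	2		
Spermidine	HMDB0001257	C7H19N3	145.15790	1	Arginine and proline metabolism;Glutathione metabolism;beta-Alanine metabolism	
N1-Acetylspermidine	HMDB0001276	C9H21N3O	187.16846	1	Arginine and proline metabolism	N1-AcetylSPD
Asymmetric dimethylarginine	HMDB0001539	C8H18N4O2	202.14298	1	Arginine and proline metabolism	ADMA
1-Methylguanosine	HMDB0001563	C11H15N5O5	297.10732	2	Purine metabolism	
Acetaminophen	HMDB0001859	C8H9NO2	151.06333	2		
Benzoic acid	HMDB0001870	C7H6O2	122.03678	2	Phenylalanine metabolism	
Omeprazole	HMDB0001913	C17H19N3O3S	345.11471	2		
2-Pyrrolidinone	HMDB0002039	C4H7NO	85.05276	2		
Carnosol	HMDB0002121	C20H26O4	330.18311	2		
Cadaverine	HMDB0002322	C5H14N2	102.11570	1	Lysine degradation	
Phenylpropiolic acid	HMDB0002359	C9H6O2	146.03678	2	Phenylalanine metabolism	
Shikimic acid	HMDB0003070	C7H10O5	174.05282	2	Phenylalanine, tyrosine and tryptophan biosynthesis	
Berberine	HMDB0003409	C20H18NO4	336.12358	2		
L-Gulonolactone	HMDB0003466	C6H10O6	178.04774	2	Ascorbate and aldarate metabolism	
19-Hydroxyandrost-4-ene-3,17-dione	HMDB0003955	C19H26O3	302.18819	2	Steroid hormone biosynthesis	
Dopamine 4-sulfate	HMDB0004148	C8H11NO5S	233.03579	2	Tyrosine metabolism	
3-Methyluridine	HMDB0004813	C10H14N2O6	258.08519	2	Pyrimidine metabolism	
Sumatriptan	HMDB0005037	C14H21N3O2S	295.13545	2		
DG(20:1/20:4/0:0)	HMDB0005233	C43H72O5	668.53798	2	Glycerolipid metabolism	
Ophthalmic acid	HMDB0005765	C11H19N3O6	289.12739	2	Glutathione metabolism	
2-Methylguanosine	HMDB0005862	C11H15N5O5	297.10732	2	Purine metabolism	
Malondialdehyde	HMDB0006112	C3H4O2	72.02113	2		
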