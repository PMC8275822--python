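id	chromosome	strand	strand_printed	genomic_start	genomic_end	length_aa	sequence
NONHSAT108542	chr6	+	+	29693230	29697128	35	MCTHDFITGHWMLIFIRSAGAQDTTLLPTGRNPLH
NONHSAT040552	chr14	-	−	106775156	106775618	37	TTSVKGRFTISRDDSKSITYLQMNSLRAEDTAVYYCA
NONHSAT051106	chr15	-	−	101040452	101069470	37	GCHPVASPHVTDCPQSEILTRNFGGWVSEGISGLTQR
NONHSAT071811	chr2	+	+	75711197	75714060	41	MGMWRTFVSSSGIVNAPITALSKQAAGLYQSAGCGWGQIRE
NONHSAT072293	chr2	-	−	89170774	89171212	43	KLENPPKLLIYAASSLPSGVPSRFSGSRSGTHFTHSHHQEPAT
NONHSAT072318	chr2	+	+	89929700	89930202	54	TISSSLAGYQWKPGQALRLLIHGASTRTTNVPAWWSGSGFGENFSLIISRLEHE
NONHSAT083836	chr22	+	+	22915634	22915927	62	KENGTLVTKGIETTTPSTQSNNNYAASSYLSLTPEQWKSHRSYSCQVTHKESTMEKTMAHAE
NONHSAT028900	chr12	-	−	57633328	57634498	63	GEGKPRRGGGAGWEWAYDPCPKPGQEPGRRGPRRRALCINRWRGRLCLTRSLTAQLPAPLLSG
NONHSAT032697	chr13	+	+	28582866	28583699	71	QGFLLRLCHDVGKREVVLTQGTEGVLAVAGGAGAAAHLRVKTTLERPSSLKFDIRIYIREFPTEAICSAGR
NONHSAT083819	chr22	+	+	22762293	22762516	73	YELTQPPAVSVSPGQTARISCSGDVLRDNYADWYPQKPGQAPVLVIYKDGERPSGIPERFSGSTSGNTTALTI
NONHSAT072624	chr2	+	+	97355058	97355335	87	MTQPPSSLSASVGDSVTITCRASQSFTNQLAWYQQKPGKAPKLLIYRVSSLQTGVPSLFSGSESGTDFTLTISSLQPDDVATYYCQQ
NONHSAT040529	chr14	-	−	106586375	106586826	88	GLVQPGGSLRLSCAASGFTFSSSWMHWVCQAPEKGLEWVADIKCDGSEKYYVDSVKGRLTISRDNAKNSLYLQVNSLRAEDMTVYYCV
NONHSAT030405	chr12	-	−	104030743	104032248	89	MKGVGAGDKMAKMKMGATGPHLQLQLKMSTDVVSVTCAGGRGRGTRWAGRVLLGTVSSPPAFTSWPCPGQPQLPWLCAPSPHPPETAWA
NONHSAT141981	chr16	+	+	31962087	31974361	95	EVQLVESGGGLVQPGGSLRLSCAASGFTFSNRSTHWVRQAPGKGLEWVGHSVSKKKKKKKKKKKKGRFTISRDDSKNTLYLQMNSLKTEDTAVYY
NONHSAT072603	chr2	+	+	97059944	97060389	107	MRIPAQLLAFLLLCLPGKEGEHWEMTQPPSSLSASVGDRVTVSCQASQSIYNYLNWYQQKPGKAPKFLTYRASSLQRGMPSQFSGSGYGRDFTLTVSSLQPEDFATY
NONHSAT040524	chr14	-	−	107034726	107034966	110	ISCKGSGYSFSTYWVGWVRQIPGKGLEWMAIIYPSDSDTRYSPSFQGQVTISADKSISTAYLQWSSLKASDTAMYYCARHGYLSSGKGYFDYWGQGTQVTVSSGSASAPT
NONHSAT142116	chr16	-	−	33938336	33938799	113	AEFSLLLFLKVSSVRCSWWSLPEALVQPGGSLRLSCAASGFTCSNAWMSWVRQAPGKGLEWVGRIKSKANGGTTDYAAPVKGRFTISRVDSKNTLYLQMNSLKTEDTAVYYCT
NONHSAT040427	chr14	-	−	105864215	106268900	125	VQLLESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSAISGSGGGTYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAKDRAPYSSSFDYWGQGTLVTVSSRSASAP
NONHSAT011749	chr10	-	−	22435424	22437929	210	GVRWIQQNKHHKKIICERRRRCCENLVPETVSEQQKNRRKPKEHDPDGDGGGARGQHCHLPPTPGLKSERRLGGHKCRLLLSFAEAEKSPSGARRASRGKRAVTIPTGRPQRSLSADKAASKGAPRLPSHHVPFGRRKRKRPLPVRQPDNSGGQAAPRQHLCFPRAGKRSLRIPQKPEADTTETRGRSSRSDVYSGRERGGHLRLGEAAG
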