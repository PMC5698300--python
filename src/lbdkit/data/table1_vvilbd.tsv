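locus_id	short_name	legacy_names	strand	start	end
Vitvi08g00144	LBDIa1	LBD20	+	2648151	2649186
Vitvi15g00736	LBDIa2	LBD19	+	14992229	14994929
Vitvi15g00735	LBDIa3		-	14983081	14985200
Vitvi07g00573	LBDIa4	LBD16	-	6228524	6229895
Vitvi13g00333	LBDIa5	LBD33	+	3457062	3457909
Vitvi07g00572	LBDIa6		+	6220003	6220810
Vitvi17g00890	LBDIc1	LOB	-	10710469	10712731
Vitvi14g01707	LBDIc2		+	27155871	27157919
Vitvi13g00085	LBDIc3	LBD21	-	817035	817745
Vitvi00g00480	LBDIc4	LBD6	+	11326893	11330106
Vitvi00g01060	LBDIc5		-	22493178	22495116
Vitvi07g01328	LBDIc6		-	18720228	18722222
Vitvi07g01326	LBDIc7		-	18699491	18702938
Vitvi07g01327	LBDIc8		-	18708083	18709964
Vitvi16g00859	LBDIc9		-	15931002	15932161
Vitvi19g01589	LBDId1	LBD3	+	21536622	21539654
Vitvi10g01237	LBDId2	LBD4	-	17047348	17048794
Vitvi06g00706	LBDId3		+	7971884	7972497
Vitvi13g00109	LBDId4		+	1022072	1022675
Vitvi13g00144	LBDId5		-	1309999	1311255
Vitvi06g00772	LBDId6	LBD13	-	8584220	8586134
Vitvi13g01866	LBDIf1		-	5100511	5101131
Vitvi13g01867	LBDIf2		-	5102158	5103523
Vitvi13g00555	LBDIf3		-	5130143	5136580
Vitvi13g00559	LBDIf4		-	5173575	5179644
Vitvi13g00551	LBDIf5		-	5061981	5063306
Vitvi13g00552	LBDIf6		-	5073630	5074839
Vitvi13g00549	LBDIf7		+	5039284	5040392
Vitvi13g00545	LBDIf8		+	4985620	4986382
Vitvi13g00546	LBDIf9		+	5011144	5011863
Vitvi13g00556	LBDIf10		-	5144789	5155693
Vitvi13g00543	LBDIf11		+	4954628	4956343
Vitvi06g00336	LBDIf12		-	4180846	4182157
Vitvi06g00338	LBDIf13		-	4201430	4202390
Vitvi16g01446	LBDIg1		+	17405415	17406086
Vitvi15g01216	LBDIi1		+	17253530	17254344
Vitvi15g01217	LBDIi2		+	17259993	17261012
Vitvi04g01768	LBDIi3		+	996279	997019
Vitvi14g01878	LBDIi4	LBD27	-	28646091	28646927
Vitvi17g00520	LBDIi5		-	6117662	6119015
Vitvi09g00188	LBDIi6	LBD22	-	2066342	2067873
Vitvi12g00230	LBDIi7	LBD2	-	3392281	3394534
Vitvi11g00169	LBDIi8		+	1720665	1722595
Vitvi14g01193	LBDIIa1		+	21211055	21212346
Vitvi17g00325	LBDIIa2		-	3791838	3793171
Vitvi01g00291	LBDIIa3		-	3210258	3211492
Vitvi01g00290	LBDIIa4		+	3204504	3205665
Vitvi18g00677	LBDIIb1		+	7746353	7747276
Vitvi07g01610	LBDIIb2	LBD39	+	21897655	21899042
Vitvi03g00628	LBDIIc1		-	7098961	7099834
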