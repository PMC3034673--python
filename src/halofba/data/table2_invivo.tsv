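entry	type	in_vivo	transport_reactions	utilization_reactions
Catalase	activity	+		rxn87
Citrate synthase	activity	+		rxn328
Urease	activity	+		rxn610
Nitrate reduction	activity	+		rxn216-rxn218
Acetate	substrate	+	rxn964	rxn527;rxn559;rxn817
Adonitol	substrate	-		
Glycine Betaine	substrate	+	rxn1112;rxn1113	rxn136;rxn137;rxn243
Butyrate	substrate	-		
Caprylate	substrate	-		
Cellobiose	substrate	-		
Choline	substrate	+	rxn1004;rxn1005	rxn83;rxn107;rxn580
Citrate	substrate	+	rxn1007	rxn328;rxn702;rxn726;rxn727
Creatine	substrate	-		
D-fructose	substrate	+	rxn1079;rxn1080	rxn62;rxn337;rxn433;rxn781
D-galactose	substrate	+	rxn1091	rxn53
D-glucose	substrate	+	rxn877;rxn881;rxn882	rxn82;rxn422
DL-glycerate	substrate	+	rxn1114	rxn64
DL-a-aminobutyrate	substrate	-		
D-mannitol	substrate	+	rxn1173	rxn33;rxn62
D-mannose	substrate	+	rxn1161	rxn33;rxn781
D-melibiose	substrate	-		
D-raffinose	substrate	-		
D-ribose	substrate	+	rxn1274	rxn418
D-sorbitol	substrate	+	rxn1284	rxn17
L-tartrate	substrate	+	rxn1312	rxn729
D-trehalose	substrate	+	rxn1327;rxn1328	rxn562
Dulcitol (galactitol)	substrate	+	rxn1101	rxn53
D-xylose	substrate	+	rxn1385	rxn22
Erythritol	substrate	+	rxn1060	rxn427
Ethanol	substrate	+	rxn1065	rxn2
Fumarate	substrate	+	rxn1081	rxn155;rxn156;rxn158-rxn162;rxn720;rxn753-rxn755
Galactosamine	substrate	-		
Gluconolactone	substrate	-		
Glutamate	substrate	+	rxn1109	rxn763;rxn854
Glycerol	substrate	+	rxn1116	rxn1;rxn429
Glycine	substrate	+	rxn1118	rxn182;rxn183;rxn257;rxn258;rxn605;rxn695;rxn802;rxn848;rxn859
Inulin	substrate	-		
Lactate	substrate	-		
L-alanine	substrate	-		
L-arabinose	substrate	+	rxn978	rxn52
L-arginine	substrate	+	rxn979	rxn275;rxn616;rxn661;rxn753;rxn807
L-asparagine	substrate	+	rxn981	rxn597
L-fucose	substrate	-		
L-glutamine	substrate	+	rxn1103	rxn175;rxn184;rxn389;rxn699;rxn806;rxn863;rxn868-rxn872
L-lysine	substrate	+	rxn1153	rxn104;rxn814
L-methionine	substrate	-		
L-ornithine	substrate	+	rxn1209	rxn267;rxn268;rxn750
L-proline	substrate	+	rxn1248	rxn195;rxn803
L-rhamnose	substrate	-		
L-serine	substrate	+	rxn1290	rxn37;rxn256;rxn257;rxn297;rxn298;rxn514-rxn520;rxn721;rxn722;rxn751;rxn799;rxn800
L-threonine	substrate	-		
L-valine	substrate	-		
Malate	substrate	+	rxn1155	rxn46;rxn47;rxn84;rxn85;rxn720
Malonate	substrate	+	rxn1156	rxn122
Maltose	substrate	+	rxn1157	rxn587
Meso-inositol	substrate	+	rxn1170	rxn96
Oxalate	substrate	-		
Propionate	substrate	+	rxn1249	rxn433
Putrescine	substrate	-		
Sarcosine	substrate	-		
Succinate	substrate	+	rxn1305	rxn97;rxn98;rxn156;rxn159;rxn160;rxn163;rxn700;rxn841
Sucrose	substrate	+	rxn883;rxn884;rxn885	rxn337
Tagatose	substrate	+	rxn1314	rxn39;rxn439
a-lactose	substrate	-		
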