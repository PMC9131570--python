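gene	chrom	start	end	annotation
Phvul.006G003700	Pv06	1376123	1378343	Bifunctional inhibitor/lipid-transfer protein/seed storage 2S albumin superfamily protein
Phvul.006G003800	Pv06	1406616	1408098	Carbohydrate-binding X8 domain superfamily protein
Phvul.006G003900	Pv06	1417873	1419245	-
Phvul.006G004000	Pv06	1454577	1457697	homolog of yeast ADA2 2B
Phvul.006G004100	Pv06	1486729	1491368	homolog of yeast ADA2 2A
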