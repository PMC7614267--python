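# glycanpipe diagnostic ion library, format v1
# columns: label, mz, mode (pos/neg), ion_type (Y1-core/Y2/B/loss/precursor-loss), composition, motif
# Y-ion compositions include the reducing-end label (PA for N-glycans); an
# empty composition marks an uninterpreted diagnostic (reported, no motif
# assertion). Loss entries are matched as precursor-minus-peak differences.
label	mz	mode	ion_type	composition	motif
446	446.2134	pos	Y1-core	HexNAc1Fuc1	proximal-state:F1G0
592	592.2713	pos	Y1-core	HexNAc1Fuc2	proximal-state:F2G0
608	608.2662	pos	Y1-core	Hex1HexNAc1Fuc1	proximal-state:F1G1
754	754.3241	pos	Y1-core	Hex1HexNAc1Fuc2	proximal-state:F2G1
770	770.3190	pos	Y1-core	Hex2HexNAc1Fuc1	proximal-state:F1G2
916	916.3769	pos	Y1-core	Hex2HexNAc1Fuc2	proximal-state:F2G2
811	811.3456	pos	Y2	Hex1HexNAc2Fuc1	distal-galfuc
369	369.1422	pos	B	HexNAc1PC1	antenna-PC-HexNAc
407	407.1661	pos	B	HexNAc2	LacdiNAc
531	531.1950	pos	B	Hex1HexNAc1PC1	antenna-Hex-HexNAc-PC
572	572.2216	pos	B	HexNAc2PC1	antenna-HexNAc2PC1
737	737.2771	pos	B	HexNAc2PC2	antenna-HexNAc2PC2
775	775.3010	pos	B	HexNAc3PC1	antenna-HexNAc3PC1
940	940.3565	pos	B	HexNAc3PC2	antenna-HexNAc3PC2
978	978.3804	pos	B	HexNAc4PC1	antenna-HexNAc4PC1
1143	1143.4359	pos	B	HexNAc4PC2	antenna-HexNAc4PC2
734	734.2744	pos	B	Hex1HexNAc2PC1	antenna-Hex-HexNAc2PC1
899	899.3299	pos	B	Hex1HexNAc2PC2	antenna-Hex-HexNAc2PC2
937	937.3538	pos	B	Hex1HexNAc3PC1	antenna-Hex-HexNAc3PC1
1102	1102.4093	pos	B	Hex1HexNAc3PC2	antenna-Hex-HexNAc3PC2
1140	1140.4332	pos	B	Hex1HexNAc4PC1	antenna-Hex-HexNAc4PC1
1305	1305.4887	pos	B	Hex1HexNAc4PC2	antenna-Hex-HexNAc4PC2
369	369.1422	pos	B-o	HexNAc1PC1	o-antenna-PC-HexNAc
545	545.1743	pos	B-o	HexNAc1HexA1PC1	o-PC-HexA-unit
543	543.1597	neg	B	HexNAc1HexA1PC1	o-PC-HexA-unit
723		neg	B
146	146.0579	pos	loss	Fuc1
160	160.0736	pos	loss	Fuc1Me1
162	162.0528	pos	loss	Hex1
203	203.0794	pos	loss	HexNAc1
165	165.0555	pos	loss	PC1
299	299.1482	pos	loss	HexNAc1
308	308.1107	pos	loss	Hex1Fuc1
607	607.2589	pos	loss	Hex1HexNAc1Fuc1	reducing-galfuc
59	59.0735	neg	precursor-loss	PC1	pc-glycan
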