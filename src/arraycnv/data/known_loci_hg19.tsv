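name	chromosome	start_bp	end_bp	cnv_type	direction
1q21.1	1	145934643	147709376	both	risk
2p16.3_NRXN1	2	50147488	51259674	loss	risk
3q29	3	195745603	197355603	loss	risk
7q11.21_ZNF92	7	64838768	64865998	both	protective
7q11.23	7	72742064	74142064	gain	risk
7q36.3_VIPR2_WDR60	7	158453198	158897237	both	risk
8q22.2_VPS13B	8	100025494	100889808	loss	risk
9p24.3_DMRT1	9	841690	969090	both	risk
13q12.11_ZMYM5	13	20411593	20437773	gain	protective
AS_PWS	15	2482000	2843000	gain	risk
15q11.2	15	22798636	23088559	loss	risk
15q13.3	15	31132708	32482708	loss	risk
16p13.11	16	1551000	1630000	gain	risk
16p11.2_distal	16	28822499	29052499	loss	risk
16p11.2_proximal	16	29652499	30202499	gain	risk
17p12	17	1416000	1543000	loss	risk
17q12	17	3481000	3620000	loss	risk
22q11.21	22	19020000	21420000	loss	risk
22q11.21	22	19020000	21420000	gain	protective
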