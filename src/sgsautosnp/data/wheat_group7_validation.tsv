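locus_name	snp_score	validation
UQ7A27	6	Failed
UQ7A1397	5	Failed
UQ7A5622	2	True SNP
UQ7A129835	5	True SNP
UQ7A9400	2	Failed
UQ7A7915	6	True SNP
UQ7A6107	6	True SNP
UQ7A2603	2	Failed
UQ7A3491	4	True SNP
UQ7A4532	6	True SNP
UQ7A100138	7	Failed
UQ7A136305	5	True SNP
UQ7A155877	4	True SNP
UQ7A180868	3	True SNP
UQ7A287189	2	Failed
UQ7A322716	11	True SNP
UQ7A57227	5	True SNP
UQ7A87191	6	Heterozygous
UQ7B21	8	Failed
UQ7B484	11	Failed
UQ7B3940	6	True SNP
UQ7B4960	5	True SNP
UQ7B5991	4	True SNP
UQ7B120997	7	Failed
UQ7B256895	11	True SNP
UQ7B64318	6	Failed
UQ7B97303	8	True SNP
UQ7D283	5	True SNP
UQ7D429	3	True SNP
UQ7D689	9	Failed
UQ7D948	9	True SNP
UQ7D1189	4	True SNP
UQ7D1491	7	True SNP
UQ7D1846	10	True SNP
UQ7D2314	2	Monomorphic
UQ7D20375	6	True SNP
UQ7D27168	2	True SNP
UQ7D38754	3	Failed
UQ7D59683	6	True SNP
UQ7D68910	3	True SNP
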