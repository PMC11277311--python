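sample	total_mutations	printed_per_mb	printed_log10
1. GBM-P	15227	362.55	2.56
1. GBM-R	25619	609.99	2.79
2. GBM-P	11898	283.29	2.45
2. GBM-R	16759	399.02	2.6
3. GBM-P	6281	149.55	2.17
3. GBM-R	39456	939.43	2.97
4. GBM-P	11858	282.33	2.45
4. GBM-R	22414	533.67	2.73
5. GBM-P	35395	842.74	2.93
5. GBM-R	45060	1072.86	3.03
6. GBM-P	9111	216.93	2.34
6. GBM-R	20473	487.45	2.69
7. GBM-P	20877	497.07	2.70
7. GBM-R	10648	253.52	2.40
8. GBM-P	17404	414.38	2.62
8. GBM-R	22285	530.6	2.72
9. GBM-P	6119	145.69	2.16
9. GBM-R	7341	174.79	2.24
10. GBM-P	11005	262.02	2.42
10. GBM-R	29776	708.95	2.85
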