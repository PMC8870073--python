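patient_id	mapped_reads_million	sequenced_reads_pct	median_insert_size	average_coverage
1	80.700	63.3	168	835.6
3	97.104	60.2	169	1001.1
4	111.257	66.9	168	1263.4
5	92.790	59.9	166	901.4
6	91.009	64.3	175	986.0
7	56.938	55.7	131	327.7
8	93.552	61.0	158	927.2
9	111.344	68.0	169	1206.1
10	105.295	68.3	167	1153.6
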