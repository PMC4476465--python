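nv_gene_id	g_factor	annotation	nv_peak	am_seqindex	am_peak
246249	0.9231	Hes/Hey-like	12pm	18661	8am (1/1)
185184	0.8102	High mobility group protein B3	12pm	7362	4am (1/1)
114661	0.8014	Heme-binding protein 2 (SOUL family)	4pm	16238	12pm (30/32)
181671	0.7892	Heat shock protein 108 (Hsp90 family)	12am	2404	4pm (5/5)
167250	0.7128	No hits	8am	18512	8pm (2/3)
193399	0.692	Protein disulfide-isomerase A4	12am	2399	4pm (1/1)
216823	0.6703	78 kDa glucose-regulated protein (Hsp70 family)	12am	12749	4pm (2/2)
194898	0.5128	Cryptochrome 2	4am	10302	12pm (2/2)
168581	0.5076	Cryptochrome 1a	12pm	10301	12pm (1/1)
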