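nv_gene_id	g_factor	annotation	nv_peak	am_seqindex	day_count	night_count	coral_block
246249	0.9231	Hes/Hey-like	12pm	18661	407	90	day
160110	0.7001	Clock	8pm	10199	681	216	day
241935	0.5782	Signal transducer and activator of transcription 5A	8am	70856	9	3	day
243788	0.5448	Pleckstrin homology domain-containing family G member 5	12pm	61779	50	14	day
194898	0.5128	Cryptochrome (NvCry2, AmCry1)	4am	10302	5724	353	day
168581	0.5076	Cryptochrome (NvCry1a, AmCRYb)	12pm	10301	1843	309	day
245026	0.9255	Clock-interacting circadian pacemaker (CIPC)	4am	90172	7	181	night
167250	0.7128	No hits	8am	18512	98	1513	night
163545	0.636	Transcription factor Sox17alphaB	8pm	3863	36	449	night
240625	0.6005	NIPA-like protein	12pm	10904	2	7	night
242499	0.5467	Sortilin-related receptor	4pm	13077	2	9	night
212997	0.5288	Protein BZZ1	12pm	18943	1	3	night
192745	0.5265	Putative adenosyl-homocysteinase 3	12pm	13339	2	14	night
98402	0.5059	Conserved oligomeric Golgi complex subunit 5 (COG5)	4pm	15726	4	18	night
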