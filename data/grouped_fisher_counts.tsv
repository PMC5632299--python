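# Grouped-term Fisher tests on candidate vs non-candidate lists (one-tailed,
# over-representation): O of n candidates vs (K-O) of (N-n) non-candidates.
group	K	N	n	O	direction	printed_p
oxphos_nuclear_pterygota	13	954	39	1	over	0.42
wing_related_pterygota	28	954	39	1	over	0.69
oxphos_nuclear_relaxed	14	1285	56	0	over	1.0
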