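strain	stage	total_bp	n_calls	avg_size_kb_printed
N4	initial	96546962	1082	89
XiaF	initial	84976008	711	119
AK	initial	190353801	640	297
NanC	initial	84063418	433	194
N4	filtered	4752536	150	32
XiaF	filtered	3337398	115	29
AK	filtered	3427899	89	39
NanC	filtered	2688123	60	45
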