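ltr_position	ref_base	alt_base	tier
43	C	T	main
95	C	T	main
100	T	C	main
180	C	T	main
254	A	G	main
706	A	G	main
765	G	A	main
456	C	T	2A
498	A	G	2A
133	A	G	2B
188	C	A	2B
252	C	G	2B
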