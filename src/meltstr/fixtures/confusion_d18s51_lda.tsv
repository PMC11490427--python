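known	(12,14)	(12,15)	(12,16)	(13,14)	(13,16)	(14,15)
(12,14)	9	1	1	4	4	1
(12,15)	7	6	2	1	3	1
(12,16)	1	1	4	1	0	7
(13,14)	0	1	1	7	0	11
(13,16)	0	0	0	1	6	5
(14,15)	0	0	0	1	1	14
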