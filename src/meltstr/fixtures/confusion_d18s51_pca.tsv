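known	(12,14)	(12,15)	(12,16)	(13,14)	(13,16)	(14,15)
(12,14)	7	3	2	5	1	2
(12,15)	6	6	4	2	2	0
(12,16)	2	2	8	1	1	0
(13,14)	4	1	1	7	6	1
(13,16)	0	1	0	1	7	5
(14,15)	1	1	0	1	6	7
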