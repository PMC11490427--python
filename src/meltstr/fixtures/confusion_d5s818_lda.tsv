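known	(10,11)	(11,11)	(11,12)	(11,13)	(12,12)	(12,13)	(13,13)
(10,11)	2	1	1	5	0	2	0
(11,11)	1	34	1	0	1	2	0
(11,12)	1	0	35	3	10	0	0
(11,13)	0	1	3	26	1	1	0
(12,12)	0	2	4	1	7	1	0
(12,13)	0	9	7	4	3	5	2
(13,13)	0	5	0	2	1	1	0
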