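known	(10,11)	(11,11)	(11,12)	(11,13)	(12,12)	(12,13)	(13,13)
(10,11)	5	1	1	3	1	0	2
(11,11)	4	14	3	1	7	1	2
(11,12)	7	0	10	9	14	10	17
(11,13)	3	9	3	3	2	6	8
(12,12)	1	7	0	1	7	4	1
(12,13)	1	1	7	1	5	5	7
(13,13)	0	1	0	0	4	2	5
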