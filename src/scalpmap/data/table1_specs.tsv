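definition	landmark_id	a	b	c	mode	decline_means
(2-7)/(7-5)	7	2	7	5	sagittal	anterior shift
(2-8)/(8-5)	8	2	8	5	direct	anterior shift
(2-9)/(9-5)	9	2	9	5	direct	anterior shift
(2-10)/(10-5)	10	2	10	5	direct	anterior shift
(2-16)/(16-5)	16	2	16	5	direct	anterior shift
(2-12)/(12-5)	12	2	12	5	direct	anterior shift
(2-15)/(15-5)	15	2	15	5	sagittal	anterior shift
(2-20)/(20-5)	20	2	20	5	direct	anterior shift
(2-13)/(13-5)	13	2	13	5	direct	anterior shift
(1-14)/(14-4)	14	1	14	4	coronal	dorsal shift
(1-20)/(20-4)	20	1	20	4	coronal	dorsal shift
(1-17)/(17-4)	17	1	17	4	coronal	dorsal shift
(1-18)/(18-4)	18	1	18	4	coronal	dorsal shift
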