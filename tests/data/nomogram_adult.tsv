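# Published adult optimal daily dose nomogram (g/day).
# columns: age weight then 20 doses for Cr {0.5,1.0,1.5,2.0,2.5} x BUN {10,20,30,40}
20	40	2.2	2	1.8	1.6	1.2	1.2	1	1	1	0.8	0.8	0.6	0.8	0.6	0.6	0.6	0.6	0.6	0.6	0.6
20	50	2.6	2.4	2	1.8	1.4	1.4	1.2	1	1	1	1	0.8	0.8	0.8	0.8	0.6	0.8	0.8	0.6	0.6
20	60	3	2.6	2.4	2.2	1.6	1.6	1.4	1.2	1.2	1.2	1	1	1	1	0.8	0.8	0.8	0.8	0.8	0.8
20	70	3.2	3	2.6	2.4	1.8	1.6	1.6	1.4	1.4	1.2	1.2	1	1.2	1	1	1	1	1	0.8	0.8
20	80	3.6	3.2	2.8	2.6	2	1.8	1.6	1.6	1.6	1.4	1.2	1.2	1.2	1.2	1	1	1.2	1	1	0.8
20	90	4	3.4	3.2	2.8	2.2	2	1.8	1.6	1.6	1.6	1.4	1.2	1.4	1.2	1.2	1	1.2	1.2	1	1
40	40	2.2	2	1.8	1.6	1.2	1.2	1	1	1	0.8	0.8	0.8	0.8	0.8	0.6	0.6	0.6	0.6	0.6	0.6
40	50	2.6	2.4	2	1.8	1.4	1.4	1.2	1.2	1.2	1	1	0.8	1	0.8	0.8	0.8	0.8	0.8	0.6	0.6
40	60	3	2.6	2.4	2.2	1.6	1.6	1.4	1.2	1.2	1.2	1	1	1	1	0.8	0.8	1	0.8	0.8	0.8
40	70	3.2	3	2.6	2.4	1.8	1.8	1.6	1.4	1.4	1.4	1.2	1	1.2	1	1	1	1	1	0.8	0.8
40	80	3.6	3.2	2.8	2.6	2	1.8	1.8	1.6	1.6	1.4	1.4	1.2	1.4	1.2	1.2	1	1.2	1	1	1
40	90	3.8	3.4	3.2	2.8	2.2	2	1.8	1.8	1.8	1.6	1.4	1.4	1.4	1.4	1.2	1.2	1.2	1.2	1	1
60	40	1.8	1.6	1.4	1.2	1	1	0.8	0.8	0.8	0.8	0.6	0.6	0.6	0.6	0.6	0.6	0.6	0.6	0.4	0.4
60	50	2	1.8	1.6	1.4	1.2	1	1	1	1	0.8	0.8	0.8	0.8	0.8	0.6	0.6	0.6	0.6	0.6	0.6
60	60	2.2	2	1.8	1.6	1.4	1.2	1.2	1	1	1	1	0.8	0.8	0.8	0.8	0.8	0.8	0.8	0.6	0.6
60	70	2.6	2.2	2	1.8	1.6	1.4	1.2	1.2	1.2	1	1	1	1	1	0.8	0.8	0.8	0.8	0.8	0.8
60	80	2.8	2.6	2.2	2	1.8	1.6	1.4	1.4	1.4	1.2	1.2	1	1.2	1	1	1	1	1	0.8	0.8
60	90	3	2.8	2.4	2.2	1.8	1.8	1.6	1.4	1.4	1.4	1.2	1.2	1.2	1.2	1	1	1	1	1	1
80	40	1.4	1.2	1.2	1	0.8	0.8	0.8	0.6	0.6	0.6	0.6	0.6	0.6	0.6	0.4	0.4	0.6	0.4	0.4	0.4
80	50	1.6	1.4	1.4	1.2	1	1	0.8	0.8	0.8	0.8	0.6	0.6	0.6	0.6	0.6	0.6	0.6	0.6	0.6	0.6
80	60	1.8	1.6	1.6	1.4	1.2	1	1	1	1	0.8	0.8	0.8	0.8	0.8	0.6	0.6	0.8	0.6	0.6	0.6
80	70	2	1.8	1.6	1.6	1.2	1.2	1.2	1	1	1	0.8	0.8	0.8	0.8	0.8	0.8	0.8	0.8	0.8	0.6
80	80	2.2	2	1.8	1.8	1.4	1.4	1.2	1.2	1.2	1	1	1	1	1	0.8	0.8	0.8	0.8	0.8	0.8
80	90	2.4	2.2	2	1.8	1.6	1.4	1.4	1.2	1.2	1.2	1.2	1	1	1	1	1	1	1	0.8	0.8
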