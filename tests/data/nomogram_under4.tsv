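# Published under-4 optimal weight-normalized daily dose nomogram (mg/kg/day).
# columns: pma weight then 16 doses for Cr {0.3,0.6,0.9,1.2} x BUN {5,10,15,20}
40	3	30	25	25	25	15	15	15	15	10	10	10	10	10	10	10	10
40	3.5	30	25	25	25	15	15	15	15	10	10	10	10	10	10	10	10
40	4	25	25	25	20	15	15	15	10	10	10	10	10	10	10	10	5
66	7	45	40	40	35	20	20	20	20	15	15	15	15	10	10	10	10
66	8	40	40	35	35	20	20	20	15	15	15	15	10	10	10	10	10
66	9	40	35	35	30	20	20	20	15	15	15	15	10	10	10	10	10
92	9	55	50	45	40	25	25	20	20	20	15	15	15	15	15	10	10
92	10.5	50	45	45	40	25	25	20	20	15	15	15	15	15	10	10	10
92	12	45	45	40	40	25	20	20	20	15	15	15	15	15	10	10	10
118	10	60	55	50	45	30	25	25	25	20	20	15	15	15	15	15	10
118	12	55	50	45	45	25	25	25	20	20	15	15	15	15	15	15	10
118	14	50	50	45	40	25	25	20	20	15	15	15	15	15	15	10	10
144	11	60	55	50	50	30	25	25	25	20	20	15	15	15	15	15	15
144	13	55	55	50	45	25	25	25	20	20	15	15	15	15	15	15	10
144	15	55	50	45	45	25	25	25	20	20	15	15	15	15	15	10	10
196	12.5	65	60	55	50	30	30	25	25	20	20	20	15	15	15	15	15
196	14.5	60	55	50	45	30	25	25	25	20	20	15	15	15	15	15	15
196	16.5	55	50	50	45	25	25	25	20	20	15	15	15	15	15	15	10
248	14	65	60	55	50	30	30	25	25	20	20	20	15	15	15	15	15
248	16.5	60	55	50	45	30	25	25	25	20	20	15	15	15	15	15	15
248	19	55	50	50	45	25	25	25	20	20	15	15	15	15	15	15	10
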