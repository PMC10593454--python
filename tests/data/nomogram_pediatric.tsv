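# Published pediatric (4-19 y) optimal weight-normalized daily dose nomogram (mg/kg/day).
# columns: age weight then 16 doses for Cr {0.5,1.0,1.5,2.0} x BUN {10,15,20,25}
6	17	50	45	40	40	25	25	20	20	20	15	15	15	15	15	15	10
6	19	45	45	40	40	25	25	20	20	15	15	15	15	15	15	10	10
6	21	45	40	40	35	25	20	20	20	15	15	15	15	15	15	10	10
6	23	45	40	40	35	25	20	20	20	15	15	15	15	15	10	10	10
6	25	40	40	35	35	20	20	20	20	15	15	15	15	15	10	10	10
10	27	45	40	40	35	25	20	20	20	15	15	15	15	15	15	10	10
10	31	40	40	35	35	20	20	20	20	15	15	15	15	15	10	10	10
10	35	40	35	35	35	20	20	20	20	15	15	15	15	10	10	10	10
10	39	40	35	35	30	20	20	20	15	15	15	15	15	10	10	10	10
10	43	35	35	30	30	20	20	20	15	15	15	15	10	10	10	10	10
14	40	40	40	35	35	20	20	20	20	15	15	15	15	10	10	10	10
14	46	40	35	35	30	20	20	20	15	15	15	15	15	10	10	10	10
14	52	35	35	30	30	20	20	20	15	15	15	15	10	10	10	10	10
14	58	35	35	30	30	20	20	15	15	15	15	15	10	10	10	10	10
14	67	35	30	30	30	20	15	15	15	15	15	10	10	10	10	10	10
18	45	40	40	35	35	20	20	20	20	15	15	15	15	15	10	10	10
18	55	40	35	35	30	20	20	20	15	15	15	15	15	10	10	10	10
18	65	35	35	30	30	20	20	15	15	15	15	15	10	10	10	10	10
18	75	35	30	30	30	20	20	15	15	15	15	10	10	10	10	10	10
18	85	35	30	30	25	20	15	15	15	15	15	10	10	10	10	10	10
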