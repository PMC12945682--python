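drug_id	model	n_abstracts	r_u	r_p	r_n	hazard_ratio	hr_p	trial_count	trial_ids
istradefylline	TxGNN	4	0.50	0.25	0.25	0.02	0.95	0
chlorpromazine	TxGNN	23	0.91	0.04	0.04	0.001	0.93	2	NCT02309723;NCT00975481
pimavanserin	TxGNN	8	0.88	0.12	0.00	12.60	0.01	4	NCT02992132;NCT03325556;NCT03118947;NCT02035553
droxidopa	TxGNN	6	0.50	0.50	0.00	0.00	0.90	0
apomorphine	TxGNN	9	0.89	0.11	0.00	67.27	<0.001	2	NCT03837067;NCT04653584
neostigmine	CompGCN	5	0.80	0.20	0.00	<0.001	0.92	0
carbamazepine	CompGCN	39	0.82	0.15	0.03	0.94	0.82	0
memantine	CompGCN	200	0.77	0.19	0.04	0.59	<0.001	97	NCT00545974;NCT01626391;NCT01409694;NCT00353665;NCT05669365
haloperidol	CompGCN	30	0.80	0.03	0.17	<0.001	0.89	4	NCT02309723;NCT00009217;NCT00000179;NCT00249145
riluzole	CompGCN	7	0.71	0.29	0.00	1.92	0.19	3	NCT00353665;NCT03605667;NCT01703117
minocycline	CompGCN	24	0.58	0.33	0.08	1.24	0.57	1	NCT01463384
magnesium	CompGCN	200	0.97	0.03	0.00	NA	NA	18	NCT04656860;NCT05728229;NCT00490568;NCT04606420;NCT04251182
carmustine	RLR	2	0.50	0.50	0.00	NA	NA	0
testosterone	RLR	103	0.94	0.05	0.01	0.84	0.27	5	NCT00392912;NCT02727699;NCT02018497;NCT00539305;NCT00000177
naproxen	RLR	37	0.76	0.05	0.19	0.94	0.38	4	NCT00007189;NCT01417130;NCT02702817;NCT00004845
doxycycline	RLR	90	0.91	0.07	0.02	0.95	0.81	4	NCT00439166;NCT04846335;NCT00715858;NCT00692588
histamine	RLR	61	0.98	0.02	0.00	NA	NA	8	NCT01268020;NCT01505504;NCT00987220;NCT06169826;NCT01009255
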