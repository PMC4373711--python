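label	dg_dn	dg_dn_err	dg_0j	dg_0j_err	rapdf_tpr
CTPRa2	3.2	0.6	3.3	0.9	-82.66
CTPRa3	4.8	0.4	6.1	1.2	-127.68
CTPRa4	4.2	1.1	9	1.5	-171.94
CTPRa5	6	0.8	11.8	1.9	-217.1
CTPRa6	7.7	0.2	14.7	2.2	-261.36
CTPRa8	14.3	1.5	20.4	2.8	-350.81
CTPRa10	23.4	2.1	26.1	3.5	-605.63
CTPR2	7.6	1.1			-154.01
CTPR3	12	0.7			-163.81
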