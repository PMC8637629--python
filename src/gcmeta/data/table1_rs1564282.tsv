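study_id	population	case_cc	case_ct	case_tt	control_cc	control_ct	control_tt
tang2013	South China	814	186	19	866	152	12
li2011	West China	616	183	13	616	142	4
chen2013	West China	285	81	10	227	48	2
lin2011	Taiwan	341	97	10	363	85	4
tseng2013_taiwan	Taiwan	381	97	5	387	104	4
tseng2013_singapore	Singapore	306	77	5	311	77	1
yu2015	West China	385	132	12	331	89	1
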