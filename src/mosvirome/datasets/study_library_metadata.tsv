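library_id	species	site	habitat	year	mosquito_count
PF4	Culex poicilipes	Younoufere	Ponds	2014	112
PF5	Culex poicilipes	Younoufere	Ponds	2015	103
PD4	Culex poicilipes	Diama	River	2014	94
PD5	Culex poicilipes	Diama	River	2015	551
PK4	Culex poicilipes	Keur Momar Sarr	Lake	2014	786
PK5	Culex poicilipes	Keur Momar Sarr	Lake	2015	383
TF4	Culex tritaeniorhynchus	Younoufere	Ponds	2014	98
TF5	Culex tritaeniorhynchus	Younoufere	Ponds	2015	85
TD4	Culex tritaeniorhynchus	Diama	River	2014	3829
TD5	Culex tritaeniorhynchus	Diama	River	2015	3921
TK4	Culex tritaeniorhynchus	Keur Momar Sarr	Lake	2014	4062
TK5	Culex tritaeniorhynchus	Keur Momar Sarr	Lake	2015	3185
DIA41	Aedes vexans	Younoufere	Ponds	2014	8640
DJI41	Aedes vexans	Younoufere	Ponds	2014	7710
NAC41	Aedes vexans	Younoufere	Ponds	2014	1590
DIA42	Aedes vexans	Younoufere	Ponds	2014	690
DIA43	Aedes vexans	Younoufere	Ponds	2014	1320
DJI51	Aedes vexans	Younoufere	Ponds	2015	132
DIA52	Aedes vexans	Younoufere	Ponds	2015	1579
DJI52	Aedes vexans	Younoufere	Ponds	2015	1041
NAC52	Aedes vexans	Younoufere	Ponds	2015	196
DIA53	Aedes vexans	Younoufere	Ponds	2015	139
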