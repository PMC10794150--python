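sample_id	variant	count
pos1	YLN	50
pos1	WHM	30
pos1	KRA	15
pos1	AAA	5
pos2	YLN	60
pos2	WHM	20
pos2	KRA	15
pos2	AAA	5
pos3	YLN	40
pos3	WHM	40
pos3	KRA	20
neg1	YLN	10
neg1	WHM	5
neg1	KRA	5
neg1	AAA	80
neg2	YLN	40
neg2	KRA	20
neg2	AAA	140
neg3	YLN	15
neg3	WHM	5
neg3	AAA	80
in1	YLN	100
in1	WHM	100
in1	AAA	200
in2	YLN	120
in2	WHM	80
in2	AAA	200
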