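sample_id	condition	replicate	monomer_label
pos1	positive	1	CbzK
pos2	positive	2	CbzK
pos3	positive	3	CbzK
neg1	negative	1	CbzK
neg2	negative	2	CbzK
neg3	negative	3	CbzK
in1	input	1	
in2	input	2	
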