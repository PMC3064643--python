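pruning	response	aicc_null	aicc_model1
1	D	5.634	-9.816
1	Dratio	-24.339	-34.464
1	Dstar	23.301	17.856
2	D	1.576	-13.352
2	Dratio	-28.703	-39.836
2	Dstar	18.922	11.193
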