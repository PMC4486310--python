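sample	condition	day	replicate
tr_d00_r1	transfected	0	1
tr_d00_r2	transfected	0	2
pa_d00_r1	parental	0	1
pa_d00_r2	parental	0	2
tr_d07_r1	transfected	7	1
tr_d07_r2	transfected	7	2
pa_d07_r1	parental	7	1
pa_d07_r2	parental	7	2
tr_d14_r1	transfected	14	1
tr_d14_r2	transfected	14	2
pa_d14_r1	parental	14	1
pa_d14_r2	parental	14	2
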