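sample	chrom	sanger_start	sanger_stop	position	reference	sanger	maq	gene
bison	chr6	88531917	88532399	88532280	A	G	G	CSN3
bison	chr6	88531917	88532399	88532296	T	C	C	CSN3
zebu	chr6	88531917	88532399	88532296	T	Y	Y	CSN3
zebu	chr6	88531917	88532399	88532332	C	M	M	CSN3
zebu	chr6	88531917	88532399	88532339	A	R	R	CSN3
zebu	chr6	88531917	88532399	88532393	G	R	R	CSN3
taurine	chr6	88531917	88532399	88532293	C	C	Y	CSN3
taurine	chr6	88531917	88532399	88532296	T	T	C	CSN3
taurine	chr6	88531917	88532399	88532393	G	G	A	CSN3
bison	chr4	95689756	95690201	95690049	T	C	C	LEPTIN
zebu	chr4	95689756	95690201	95690049	T	C	C	LEPTIN
taurine	chr4	95689756	95690201	95690049	T	C	C	LEPTIN
bison	chr10	3941758	3942115	3941786	T	C	C	TICAM2
bison	chr10	3941758	3942115	3941805	A	G	G	TICAM2
bison	chr10	3941758	3942115	3941921	A	G	G	TICAM2
bison	chr10	3941758	3942115	3941934	G	A	A	TICAM2
bison	chr10	3941758	3942115	3941946	A	G	G	TICAM2
zebu	chr10	3941758	3942115	3941921	A	G	G	TICAM2
zebu	chr10	3941758	3942115	3941946	A	R	R	TICAM2
zebu	chr10	3941758	3942115	3941963	C	Y	Y	TICAM2
taurine	chr10	3941758	3942115	3941921	A	R	R	TICAM2
bison	chr17	4284137	4284804	4284160	T	A	A	TLR2
bison	chr17	4284137	4284804	4284210	A	G	G	TLR2
bison	chr17	4284137	4284804	4284358	C	Y	Y	TLR2
bison	chr17	4284137	4284804	4284655	T	C	C	TLR2
bison	chr17	4284137	4284804	4284747	C	T	T	TLR2
zebu	chr17	4284137	4284804	4284160	T	W	W	TLR2
zebu	chr17	4284137	4284804	4284210	A	G	G	TLR2
zebu	chr17	4284137	4284804	4284652	G	K	K	TLR2
zebu	chr17	4284137	4284804	4284655	T	Y	Y	TLR2
taurine	chr17	4284137	4284804	4284210	A	R	R	TLR2
taurine	chr17	4284137	4284804	4284639	G	G	R	TLR2
taurine	chr17	4284137	4284804	4284652	G	K	K	TLR2
taurine	chr17	4284137	4284804	4284655	T	T	Y	TLR2
bison	chr8	112427182	112427427	112427204	C	T	T	TLR4
bison	chr8	112427182	112427427	112427213	C	T	T	TLR4
bison	chr8	112427182	112427427	112427326	A	C	C	TLR4
bison	chr8	112431812	112432152	112431927	G	A	A	TLR4
bison	chr8	112434757	112435132	112435011	A	C	C	TLR4
bison	chr8	112434757	112435132	112435120	C	A	A	TLR4
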