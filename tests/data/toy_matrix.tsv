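gene	tf000	tf001	tf002	tf003	tf004	tf005	tf006	tf007
g0000	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0001	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0002	not_regulated	not_regulated	up	not_regulated	TFBS	not_regulated	not_regulated	not_regulated
g0003	not_regulated	down	not_regulated	not_regulated	not_regulated	not_regulated	NDTFBS	not_regulated
g0004	down	not_regulated	not_regulated	not_regulated	not_regulated	down	up	not_regulated
g0005	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0006	not_regulated	down	not_regulated	not_regulated	up	down	up	not_regulated
g0007	not_regulated	not_regulated	not_regulated	TFBS	up	not_regulated	not_regulated	not_regulated
g0008	not_regulated	not_regulated	down	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0009	not_regulated	up	NDTFBS	not_regulated	down	not_regulated	not_regulated	not_regulated
g0010	down	not_regulated	up	not_regulated	not_regulated	not_regulated	up	down
g0011	not_regulated	not_regulated	not_regulated	down	not_regulated	not_regulated	not_regulated	not_regulated
g0012	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	down	up	not_regulated
g0013	not_regulated	not_regulated	not_regulated	up	not_regulated	down	not_regulated	TFBS
g0014	not_regulated	not_regulated	not_regulated	down	not_regulated	not_regulated	not_regulated	down
g0015	not_regulated	not_regulated	up	down	not_regulated	not_regulated	not_regulated	not_regulated
g0016	not_regulated	not_regulated	not_regulated	up	not_regulated	not_regulated	not_regulated	not_regulated
g0017	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0018	not_regulated	not_regulated	not_regulated	not_regulated	up	not_regulated	not_regulated	up
g0019	not_regulated	not_regulated	down	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0020	not_regulated	not_regulated	not_regulated	not_regulated	up	not_regulated	not_regulated	not_regulated
g0021	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0022	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	up
g0023	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0024	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0025	TFBS	not_regulated	not_regulated	not_regulated	down	not_regulated	not_regulated	not_regulated
g0026	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0027	not_regulated	not_regulated	not_regulated	down	not_regulated	up	down	not_regulated
g0028	not_regulated	not_regulated	down	not_regulated	not_regulated	not_regulated	down	not_regulated
g0029	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0030	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0031	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	down	not_regulated	not_regulated
g0032	up	not_regulated	up	not_regulated	TFBS	not_regulated	not_regulated	not_regulated
g0033	not_regulated	not_regulated	not_regulated	TFBS	down	up	not_regulated	not_regulated
g0034	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0035	not_regulated	up	up	not_regulated	down	down	not_regulated	not_regulated
g0036	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	up
g0037	down	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0038	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0039	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0040	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	up	not_regulated	not_regulated
g0041	not_regulated	not_regulated	up	up	not_regulated	not_regulated	not_regulated	not_regulated
g0042	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0043	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	up
g0044	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	down	not_regulated	not_regulated
g0045	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	down	down	up
g0046	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0047	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0048	down	up	down	not_regulated	not_regulated	down	not_regulated	not_regulated
g0049	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	up	up	not_regulated
g0050	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0051	not_regulated	not_regulated	not_regulated	not_regulated	down	not_regulated	not_regulated	not_regulated
g0052	not_regulated	down	not_regulated	not_regulated	down	not_regulated	not_regulated	not_regulated
g0053	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	down	up	not_regulated
g0054	up	not_regulated	not_regulated	not_regulated	not_regulated	up	up	not_regulated
g0055	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0056	down	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0057	down	not_regulated	not_regulated	not_regulated	not_regulated	TFBS	down	down
g0058	not_regulated	not_regulated	down	not_regulated	not_regulated	not_regulated	not_regulated	not_regulated
g0059	not_regulated	not_regulated	not_regulated	up	not_regulated	not_regulated	not_regulated	not_regulated
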