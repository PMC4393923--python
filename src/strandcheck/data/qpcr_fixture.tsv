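gene	role	rpkm_ss	rpkm_nss	Ct1	Ct2	Ct3
AMDHD2	target	3.58544	8.16441	26.30301	26.51864	26.41083
ATP6V1C2	target	2.31219	32.661	32.18005	31.57895	31.8795
COX11	target	23.49104	32.56102	21.27819	21.27837	21.27828
DALRD3	target	5.24003	17.97184	23.26547	23.24969	23.25758
MXD3	target	1.509837	8.58014	36.06333	35.29247	35.6779
POLR2I	target	8.01706	25.9707	19.39868	19.42806	19.41337
SDR39U1	target	6.96971	20.5453	23.02526	23.05474	23.04
SYNC	target	1.306066	5.69769	28.14738	28.05567	28.10153
TMOD1	target	1.30033	4.32226	27.98307	27.84805	27.91556
EEF1A1	internal_control	2248.53	2270.11	13.11139	13.15321	13.13354
HPRT1	internal_control	28.0151	28.3254	20.88358	21.07696	20.98027
TMEM66	internal_control	126.355	126.437	18.85524	18.85882	18.85703
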