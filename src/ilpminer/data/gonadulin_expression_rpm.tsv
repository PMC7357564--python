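species	tissue	rpm
Blattella germanica	Male heads	0.00
Blattella germanica	Female gonads and fat body	7.30
Blattella germanica	Male gonads and fat body	4.10
Blattella germanica	Non-fecundated eggs	493.70
Timema cristinae	Head	0.00
Timema cristinae	Testis	23.30
Timema cristinae	Ovary	46.90
Rhodnius prolixus	Ovary	78.40
Rhodnius prolixus	Testis	1.40
Rhodnius prolixus	CNS	0.20
Rhodnius prolixus	Antenna	3.00
Apis mellifera	Ovary of virgin queen	0.20
Apis mellifera	Ovary of normal egg-laying queen	61.60
Apis mellifera	Ovary of normal egg-laying inhibted queen	96.70
Apis mellifera	Ovary of normal egg-laying recovered queen	59.00
Apis mellifera	Antenna	7.10
Apis mellifera	Second thoracic ganglion	4.10
Steatoda grossa	Cephalothorax	0.00
Steatoda grossa	Ovary with eggs	7.10
Steatoda grossa	Minor ampullate silk glands	5.90
Steatoda grossa	Tubuliform silk glands	3.30
Parasteatoda tepidariorum	Ovary from SRR1824489	2.00
Parasteatoda tepidariorum	Ovary from SRR8755633	0.00
Parasteatoda tepidariorum	Ovary from SRR8755634	0.00
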