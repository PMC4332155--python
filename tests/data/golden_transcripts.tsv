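transcript_id	v_hat	se_v	tau_bar	lifetime_consistent	synthesis_time	ratio	p_cotx	n_bins	length	qc_status	discard_reasons
tu000	61.71977652991364	19.031516190659918	4.9040198621691165	True	0.6821152370763276	0.13909308205261195	0.12985297038305008	8	2526	ok	
tu001	22.112478263300474	2.5454796977930356	1.1040926386799355	True	1.8473732122463054	1.6732048992329518	0.8123552814910193	8	2451	ok	
tu002	38.09439004366287	3.1461549957431845	0.36510050754607326	False	3.682081968129596	10.085118733133895	0.9999583045577266	28	8416	ok	
tu003	23.822993947909737	1.6262974049018608	3.1821645394786673	True	1.726623170172212	0.542593932133718	0.4187613982316314	8	2468	ok	
tu004	30.844623972356853	0.44987512443258804	3.380338601995822	True	6.98284840581494	2.0657245406398403	0.8732735611582241	43	12923	ok	
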