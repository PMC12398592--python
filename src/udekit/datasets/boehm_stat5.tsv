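observableId	time	measurement
pSTAT5A_rel	0	7.901072999
pSTAT5A_rel	2.5	66.36349397
pSTAT5A_rel	5	81.17132392
pSTAT5A_rel	10	94.73030806
pSTAT5A_rel	15	95.11648305
pSTAT5A_rel	20	91.44171655
pSTAT5A_rel	30	91.25709923
pSTAT5A_rel	40	93.67229784
pSTAT5A_rel	50	88.75423282
pSTAT5A_rel	60	85.26970322
pSTAT5A_rel	80	81.13239534
pSTAT5A_rel	100	76.13592848
pSTAT5A_rel	120	65.24805913
pSTAT5A_rel	160	42.59977094
pSTAT5A_rel	200	25.15779754
pSTAT5A_rel	240	15.4301824
pSTAT5B_rel	0	4.596533343
pSTAT5B_rel	2.5	29.63454599
pSTAT5B_rel	5	46.04380647
pSTAT5B_rel	10	81.97473362
pSTAT5B_rel	15	80.5716093
pSTAT5B_rel	20	79.03571964
pSTAT5B_rel	30	75.67238037
pSTAT5B_rel	40	71.62471986
pSTAT5B_rel	50	69.06286328
pSTAT5B_rel	60	67.14738432
pSTAT5B_rel	80	60.89947629
pSTAT5B_rel	100	54.80925777
pSTAT5B_rel	120	43.98128998
pSTAT5B_rel	160	29.77145816
pSTAT5B_rel	200	20.08901656
pSTAT5B_rel	240	10.96184517
rSTAT5A_rel	0	14.72316822
rSTAT5A_rel	2.5	33.76234229
rSTAT5A_rel	5	36.79985129
rSTAT5A_rel	10	49.71760229
rSTAT5A_rel	15	46.9281201
rSTAT5A_rel	20	47.83657456
rSTAT5A_rel	30	46.92872725
rSTAT5A_rel	40	40.59775294
rSTAT5A_rel	50	43.78366389
rSTAT5A_rel	60	44.45738765
rSTAT5A_rel	80	41.32715926
rSTAT5A_rel	100	41.06273321
rSTAT5A_rel	120	39.23583003
rSTAT5A_rel	160	36.61946054
rSTAT5A_rel	200	34.8937144
rSTAT5A_rel	240	32.21107716
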