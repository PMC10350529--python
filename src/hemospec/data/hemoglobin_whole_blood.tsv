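wavelength_nm	mu_a_oxy_per_cm	mu_a_deoxy_per_cm
500.0	112.08770038732877	111.71286095358555
502.0	111.18327562334109	114.31064837455222
504.0	110.25078528955044	118.2159898376266
506.0	109.20844998793858	123.29354448587547
508.0	107.93063614838744	130.66946223540685
510.0	107.28440078636211	138.01052465519894
512.0	108.61741508939882	143.95569294608887
514.0	111.7234701599248	149.61884701715542
516.0	115.66731316924866	155.76341929525773
518.0	121.75214474428405	162.32104125592699
520.0	129.59805679219045	169.15432675020676
522.0	139.80985292175663	176.18302286246512
524.0	153.0714332508449	183.54146655775392
526.0	169.92407566501686	191.52006404096448
528.0	193.1594191955535	200.25826724902493
530.0	213.95834878062814	209.03188765143156
532.0	227.76484608350438	217.54810356717272
534.0	239.7314932011728	225.9354759505247
536.0	254.86734176456113	234.03078045245783
538.0	274.8174524564146	241.86603877527304
540.0	285.0707442107698	249.4931270994851
542.0	282.7601859703015	256.8989192083393
544.0	276.88133109715596	264.13949241011323
546.0	266.25950644522794	271.30415212867473
548.0	246.32305645982817	278.4521507806753
550.0	230.34418688426018	286.01319764418133
552.0	211.19718125988967	289.4513793301748
554.0	193.0877710969321	291.54167331534956
556.0	183.56900384299408	291.6433335757416
558.0	177.24592802648075	290.27126668587835
560.0	174.63769218096468	288.02662088828777
562.0	177.17579375023573	283.02876822782366
564.0	183.47549147466736	274.85348682132235
566.0	193.83451571550495	265.4033724144997
568.0	215.6333924500882	253.14454753132523
570.0	238.2693634834025	241.4608535192733
572.0	258.23204735202506	232.15474452112696
574.0	275.7310028555899	223.6951600204532
576.0	284.7560504806224	215.5407947711507
578.0	283.6579237784255	207.2782268734368
580.0	268.2993569752876	198.2365119596269
582.0	242.8332947804425	187.97410884089533
584.0	206.63328840095542	176.9372134291439
586.0	165.0944710275026	165.78800851417333
588.0	111.83867392807592	154.46488256254003
590.0	72.2904622219061	142.59427544497314
592.0	53.25804264648352	129.69717088246236
594.0	39.969509068135004	116.30004953396676
596.0	30.17705948220037	103.11326596922666
598.0	22.322213366548752	89.53685479417902
600.0	17.13551697111848	78.59311955784561
602.0	14.186372103839199	71.26363916657965
604.0	12.103794809099332	65.39433711319494
606.0	10.459733451728079	59.94907923410631
608.0	9.120943635599096	54.91358535404259
610.0	8.064402674532635	50.565839611959944
612.0	7.228897382320429	46.9958912964465
614.0	6.544108963898079	43.85096444088968
616.0	5.970296546658148	40.702166178989636
618.0	5.491458688960071	37.51751637880185
620.0	5.044267808373003	34.86006733811916
622.0	4.581032180251953	32.88119159568905
624.0	4.147110256491162	31.247879540685283
626.0	3.80113272822535	29.851034273220698
628.0	3.51734199770734	28.655086396127306
630.0	3.2664579226194603	27.57211777634033
632.0	3.0324144330574136	26.54808624636569
634.0	2.8227792989324882	25.604827096683632
636.0	2.6463829276328394	24.755516193726457
638.0	2.4928483961305177	23.989528747152587
640.0	2.3668432816357403	23.26681913734681
642.0	2.268913950854723	22.568046987856906
644.0	2.1864258750196806	21.90142811856762
646.0	2.109043680417803	21.268122185529098
648.0	2.037348738147965	20.66848879583842
650.0	1.9705844516786253	20.081326532415886
652.0	1.9065802197096677	19.49462572295022
654.0	1.84722897358737	18.91744517066359
656.0	1.7960260036265119	18.35548184455816
658.0	1.7508518639885837	17.805500301706356
660.0	1.7114097574904583	17.277741761978763
662.0	1.6772163810991516	16.776862243728374
664.0	1.6470432846211613	16.297254067526797
666.0	1.620199542592816	15.83797864787706
668.0	1.5962435543822873	15.400635950830665
670.0	1.5743256217215105	14.966803104461299
672.0	1.5539028020982866	14.52144238420671
674.0	1.5350146560925728	14.080257062531908
676.0	1.5171033097833126	13.666814107350435
678.0	1.499246379188921	13.279133615852064
680.0	1.4865060972445283	12.894476520766657
682.0	1.4786381532720696	12.50024564772554
684.0	1.473372066196505	12.10708916131245
686.0	1.4728466422875508	11.72194553940447
688.0	1.474731549154374	11.33827522593112
690.0	1.4779383387589689	10.988150257729727
692.0	1.4870446420636205	10.690153596296968
694.0	1.5023197314778747	10.417533544521946
696.0	1.5176804984769845	10.143845479025222
698.0	1.5344121068337837	9.872663967945433
700.0	1.552906225507612	9.606599201933298
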