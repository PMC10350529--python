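wavelength_nm	mu_s_white_per_cm	mu_s_gray_per_cm	g_white	g_gray
500.0	501.23487563599934	156.60327763382193	0.8	0.88
502.0	499.43726056648666	155.60620351217347	0.801	0.8804
504.0	497.65320163881677	154.619404401812	0.802	0.8808
506.0	495.8825434355892	153.64273427073167	0.803	0.8812
508.0	494.1251329262052	152.6760497284693	0.804	0.8816
510.0	492.3808194209944	151.7192099681624	0.805	0.882
512.0	490.64945452639915	150.77207671009936	0.806	0.8824
514.0	488.93089210118825	149.8345141467178	0.807	0.8828
516.0	487.22498821367157	148.90638888900781	0.808	0.8832
518.0	485.53160109989017	147.98756991427996	0.809	0.8836
520.0	483.85059112275445	147.07792851525707	0.81	0.884
522.0	482.1818207321074	146.17733825045264	0.811	0.8844
524.0	480.5251544256863	145.28567489579672	0.812	0.8848
526.0	478.88045871096085	144.40281639747553	0.8130000000000001	0.8852
528.0	477.2476020678242	143.528642825948	0.8140000000000001	0.8856
530.0	475.6264549121147	142.66303633110633	0.8150000000000001	0.886
532.0	474.0168895599475	141.805881098548	0.8160000000000001	0.8864
534.0	472.41878019283337	140.9570633069278	0.8170000000000001	0.8868
536.0	470.8320028235667	140.11647108635816	0.8180000000000001	0.8872
538.0	469.25643526286086	139.28399447782965	0.8190000000000001	0.8876000000000001
540.0	467.69195708671356	138.45952539362202	0.8200000000000001	0.888
542.0	466.13844960448273	137.64295757867873	0.8210000000000001	0.8884
544.0	464.595795827654	136.834186572917	0.8220000000000001	0.8888
546.0	463.063880439285	136.03310967444855	0.8230000000000001	0.8892
548.0	461.5425897641061	135.23962590368535	0.8240000000000001	0.8896000000000001
550.0	460.0318117392638	134.45363596830538	0.8250000000000001	0.89
552.0	458.53143588568923	133.67504222905575	0.8260000000000001	0.8904
554.0	457.04135328007663	132.9037486663696	0.8270000000000001	0.8908
556.0	455.56145652745687	132.13966084777445	0.8280000000000001	0.8912
558.0	454.0916397343503	131.38268589607105	0.8290000000000001	0.8916
560.0	452.63179848248683	130.6327324582614	0.8300000000000001	0.892
562.0	451.1818298030762	129.88971067520546	0.8310000000000001	0.8924
564.0	449.74163215161815	129.15353215198775	0.8320000000000001	0.8928
566.0	448.3111053832367	128.42410992897413	0.8330000000000001	0.8932
568.0	446.89015072852783	127.70135845354034	0.8340000000000001	0.8936
570.0	445.4786707699067	126.98519355245466	0.8350000000000001	0.894
572.0	444.0765694184429	126.27553240489735	0.8360000000000001	0.8944
574.0	442.6837518911724	125.5722935160997	0.8370000000000001	0.8948
576.0	441.3001246888739	124.87539669158669	0.8380000000000001	0.8952
578.0	439.9255955742992	124.18476301200714	0.8390000000000001	0.8956
580.0	438.5600735508467	123.50031480853625	0.8400000000000001	0.896
582.0	437.2034688416671	122.82197563883535	0.8410000000000001	0.8964
584.0	435.855692869191	122.14967026355441	0.8420000000000001	0.8968
586.0	434.51665823507034	121.48332462336356	0.8430000000000001	0.8972
588.0	433.18627870051995	120.8228658164992	0.8440000000000001	0.8976
590.0	431.86446916705484	120.16822207681258	0.8450000000000001	0.898
592.0	430.55114565760977	119.51932275230688	0.8460000000000001	0.8984
594.0	429.24622529803526	118.87609828415091	0.8470000000000001	0.8988
596.0	427.9496262989585	118.23848018615719	0.8480000000000001	0.8992
598.0	426.66126793800345	117.6064010247124	0.8490000000000001	0.8996
600.0	425.3810705423608	116.97979439914923	0.8500000000000001	0.9
602.0	424.1089554716984	116.35859492254772	0.8510000000000001	0.9004
604.0	422.8448451014067	115.74273820295636	0.8520000000000001	0.9008
606.0	421.5886628061702	115.13216082502106	0.8530000000000001	0.9012
608.0	420.3403329438577	114.52680033201341	0.8540000000000001	0.9016
610.0	419.09978083972425	113.92659520824682	0.8550000000000001	0.902
612.0	417.8669327709177	113.33148486187174	0.8560000000000001	0.9024
614.0	416.64171595128346	112.74140960804057	0.8570000000000001	0.9028
616.0	415.42405851645964	112.15631065243277	0.8580000000000001	0.9032
618.0	414.2138895092575	111.5761300751314	0.8590000000000001	0.9036
620.0	413.01113886532	111.00081081484305	0.8600000000000001	0.904
622.0	411.81573739905235	110.43029665345188	0.8610000000000001	0.9044
624.0	410.6276167898183	109.8645322009002	0.8620000000000001	0.9048
626.0	409.44670956839803	109.30346288038778	0.863	0.9052
628.0	408.2729491036984	108.7470349138816	0.8640000000000001	0.9056
630.0	407.10626958971454	108.19519530792932	0.865	0.906
632.0	405.9466060327329	107.64789183976836	0.8660000000000001	0.9064
634.0	404.7938942387735	107.10507304372415	0.867	0.9068
636.0	403.64807080126525	106.56668819789043	0.8680000000000001	0.9072
638.0	402.50907308894915	106.03268731108486	0.869	0.9076
640.0	401.37683923400385	105.50302111007313	0.8700000000000001	0.908
642.0	400.25130812039083	104.97764102705607	0.871	0.9084
644.0	399.13241937241213	104.45649918741243	0.8720000000000001	0.9088
646.0	398.02011334347714	103.9395483976922	0.873	0.9092
648.0	396.9143311050749	103.42674213385425	0.8740000000000001	0.9096
650.0	395.81501443594567	102.91803452974253	0.875	0.91
652.0	394.7221058114485	102.41338036579536	0.8760000000000001	0.9104
654.0	393.6355483931215	101.91273505798256	0.877	0.9108
656.0	392.5552860184295	101.41605464696478	0.8780000000000001	0.9112
658.0	391.4812631906948	100.92329578747011	0.879	0.9116
660.0	390.41342506920955	100.43441573788319	0.88	0.912
662.0	389.35171745952306	99.94937235004153	0.881	0.9124
664.0	388.2960868039021	99.4681240592344	0.8820000000000001	0.9128000000000001
666.0	387.2464801719609	98.99062987440007	0.883	0.9132
668.0	386.2028452514559	98.51684936851633	0.884	0.9136
670.0	385.1651303392425	98.0467426691801	0.885	0.914
672.0	384.1332843323917	97.58027044937232	0.886	0.9144
674.0	383.1072567194616	97.1173939184031	0.887	0.9148000000000001
676.0	382.08699757192034	96.6580748130336	0.888	0.9152
678.0	381.0724575357208	96.20227538877104	0.889	0.9156
680.0	380.0635878230188	95.74995841133182	0.89	0.916
682.0	379.0603402040365	95.30108714827037	0.891	0.9164
684.0	378.06266699906547	94.85562536076907	0.892	0.9168000000000001
686.0	377.0705210706071	94.41353729558598	0.893	0.9172
688.0	376.08385581564835	93.97478767715724	0.894	0.9176
690.0	375.10262515806966	93.53934169985004	0.895	0.918
692.0	374.1267835411814	93.10716502036342	0.896	0.9184
694.0	373.15628592038877	92.67822375027356	0.897	0.9188000000000001
696.0	372.1910877559795	92.25248444872025	0.898	0.9192
698.0	371.23114500603447	91.82991411523135	0.899	0.9196
700.0	370.27641411945797	91.4104801826829	0.9	0.92
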