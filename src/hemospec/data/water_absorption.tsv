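wavelength_nm	mu_a_per_cm
500.0	0.00025
502.0	0.0002637804054054054
504.0	0.00027810810810810813
506.0	0.00029296283783783786
508.0	0.00030832432432432435
510.0	0.0003241722972972973
512.0	0.0003404864864864865
514.0	0.0003572466216216216
516.0	0.00037443243243243243
518.0	0.00039202364864864865
520.0	0.00041
522.0	0.00042914605723370425
524.0	0.00044994874403815583
526.0	0.00047194131955484897
528.0	0.0004946570429252783
530.0	0.0005176291732909379
532.0	0.0005403909697933228
534.0	0.0005624756915739268
536.0	0.0005834165977742448
538.0	0.0006027469475357711
540.0	0.00062
542.0	0.0006349689514066496
544.0	0.0006481065984654731
546.0	0.0006599356010230179
548.0	0.0006709786189258312
550.0	0.0006817583120204603
552.0	0.0006927973401534527
554.0	0.0007046183631713555
556.0	0.0007177440409207161
558.0	0.0007326970332480818
560.0	0.00075
562.0	0.0007697417302573203
564.0	0.0007918160070984917
566.0	0.0008164529813664596
568.0	0.0008438828039041703
570.0	0.0008743356255545697
572.0	0.0009080415971606035
574.0	0.0009452308695652175
576.0	0.0009861335936113577
578.0	0.00103097992014197
580.0	0.00108
582.0	0.001145629964321393
584.0	0.0012365237733694878
586.0	0.0013472383216783217
588.0	0.0014723305037819324
590.0	0.0016063572142143573
592.0	0.0017438753475096335
594.0	0.0018794417982017986
596.0	0.0020076134608248896
598.0	0.002122947229912944
600.0	0.00222
602.0	0.0023048626573426577
604.0	0.0023856704895104893
606.0	0.0024600469930069926
608.0	0.002525615664335664
610.0	0.00258
612.0	0.0026240188235294114
614.0	0.002661656470588235
616.0	0.002695284705882353
618.0	0.002727275294117647
620.0	0.00276
622.0	0.0027935460392156863
624.0	0.0028263792941176473
626.0	0.002858439529411765
628.0	0.0028896665098039212
630.0	0.00292
632.0	0.002949114091127098
634.0	0.002977102273381295
636.0	0.0030045334100719423
638.0	0.003031976364508393
640.0	0.00306
642.0	0.003088012079007869
644.0	0.0031156370486819735
646.0	0.003143768799364963
648.0	0.0031733012213994902
650.0	0.003205128205128205
652.0	0.003238937703307511
654.0	0.003274424897832963
656.0	0.0033124945227559423
658.0	0.0033540513121278277
660.0	0.0034
662.0	0.0034519975776892424
664.0	0.0035106572749003984
666.0	0.0035753181832669325
668.0	0.003645319394422311
670.0	0.00372
672.0	0.003799872
674.0	0.003886656
676.0	0.003981504
678.0	0.0040855679999999995
680.0	0.0042
682.0	0.004328878431372549
684.0	0.004474635294117647
686.0	0.0046359529411764714
688.0	0.004811513725490196
690.0	0.005
692.0	0.005206726274509805
694.0	0.0054363670588235295
696.0	0.005686644705882353
698.0	0.005955281568627451
700.0	0.00624
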