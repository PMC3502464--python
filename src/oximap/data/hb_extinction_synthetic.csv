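wavelength_nm,eps_oxy,eps_deoxy
440.0,100000.00,155000.00
441.0,95404.65,147915.24
442.0,90952.98,141053.86
443.0,86664.21,134491.59
444.0,82557.51,128304.15
445.0,78652.09,122567.28
446.0,74967.14,117356.71
447.0,71521.87,112748.16
448.0,68335.45,108817.38
449.0,65427.10,105640.08
450.0,62816.00,103292.00
451.0,60438.82,101537.47
452.0,58212.02,100054.81
453.0,56124.51,98790.80
454.0,54165.20,97692.18
455.0,52322.98,96705.71
456.0,50586.76,95778.14
457.0,48945.45,94856.23
458.0,47387.95,93886.74
459.0,45903.17,92816.41
460.0,44480.00,91592.00
461.0,43108.39,90249.75
462.0,41786.76,88863.07
463.0,40516.74,87434.48
464.0,39299.97,85966.48
465.0,38138.07,84461.60
466.0,37032.69,82922.35
467.0,35985.46,81351.25
468.0,34998.02,79750.82
469.0,34071.98,78123.56
470.0,33209.00,76472.00
471.0,32392.47,74788.59
472.0,31605.99,73065.06
473.0,30851.51,71302.80
474.0,30130.96,69503.21
475.0,29446.29,67667.68
476.0,28799.44,65797.62
477.0,28192.34,63894.43
478.0,27626.95,61959.49
479.0,27105.18,59994.22
480.0,26629.00,58000.00
481.0,26190.14,55889.34
482.0,25777.65,53610.81
483.0,25389.47,51219.91
484.0,25023.51,48772.16
485.0,24677.70,46323.05
486.0,24349.95,43928.11
487.0,24038.18,41642.82
488.0,23740.32,39522.70
489.0,23454.29,37623.26
490.0,23178.00,36000.00
491.0,22905.41,34579.14
492.0,22634.18,33245.85
493.0,22367.79,31994.01
494.0,22109.74,30817.54
495.0,21863.52,29710.34
496.0,21632.62,28666.31
497.0,21420.52,27679.36
498.0,21230.73,26743.39
499.0,21066.73,25852.30
500.0,20932.00,25000.00
501.0,20810.96,24183.09
502.0,20694.31,23411.21
503.0,20594.98,22697.77
504.0,20525.90,22056.23
505.0,20500.00,21500.00
506.0,20590.45,20966.18
507.0,20825.35,20429.45
508.0,21150.03,19959.64
509.0,21509.80,19626.55
510.0,21850.00,19500.00
511.0,22169.53,19526.40
512.0,22507.96,19599.20
513.0,22871.63,19708.80
514.0,23266.86,19845.60
515.0,23700.00,20000.00
516.0,24179.21,20246.40
517.0,24710.19,20627.20
518.0,25295.56,21084.80
519.0,25937.96,21561.60
520.0,26640.00,22000.00
521.0,27425.65,22378.67
522.0,28312.08,22736.00
523.0,29291.67,23104.00
524.0,30356.85,23514.67
525.0,31500.00,24000.00
526.0,32803.23,24621.80
527.0,34294.15,25385.41
528.0,35883.45,26238.12
529.0,37481.84,27127.22
530.0,39000.00,28000.00
531.0,40448.13,28851.72
532.0,41886.45,29718.68
533.0,43300.71,30609.79
534.0,44676.65,31533.93
535.0,46000.00,32500.00
536.0,47326.25,33516.64
537.0,48667.98,34581.93
538.0,49946.59,35688.89
539.0,51083.47,36830.57
540.0,52000.00,38000.00
541.0,52813.04,39242.83
542.0,53236.00,40500.00
543.0,53062.37,41697.39
544.0,52614.08,42866.11
545.0,52000.00,44000.00
546.0,50724.53,45078.36
547.0,48778.41,46124.89
548.0,47000.00,47200.00
549.0,45748.71,48388.07
550.0,44500.00,49500.00
551.0,42868.40,50497.53
552.0,40957.16,51500.38
553.0,39011.71,52395.66
554.0,37277.51,53070.50
555.0,36000.00,53412.00
556.0,35029.38,53538.92
557.0,34113.76,53643.14
558.0,33345.44,53721.51
559.0,32816.75,53770.85
560.0,32620.00,53788.00
561.0,32747.06,53537.61
562.0,33096.37,52885.30
563.0,33620.15,51979.39
564.0,34270.62,50968.19
565.0,35000.00,50000.00
566.0,36112.40,49042.72
567.0,37793.72,47984.86
568.0,39818.85,46855.63
569.0,41962.65,45684.27
570.0,44000.00,44500.00
571.0,45997.62,43234.61
572.0,48000.00,42000.00
573.0,49992.79,40946.93
574.0,51928.74,39973.47
575.0,53500.00,39000.00
576.0,54841.58,38033.02
577.0,55540.00,37000.00
578.0,54631.85,35736.36
579.0,52492.59,34338.55
580.0,50000.00,33000.00
581.0,47188.47,31755.56
582.0,43739.16,30562.96
583.0,40000.00,29500.00
584.0,35785.96,28579.57
585.0,31195.11,27751.73
586.0,27000.00,27000.00
587.0,23237.58,26352.78
588.0,19623.27,25784.94
589.0,16447.32,25199.62
590.0,14000.00,24500.00
591.0,12158.43,23577.92
592.0,10578.78,22460.62
593.0,9219.93,21254.36
594.0,8040.72,20065.40
595.0,7000.00,19000.00
596.0,6022.11,18017.19
597.0,5096.55,17040.48
598.0,4279.93,16122.88
599.0,3628.88,15317.39
600.0,3200.00,14677.00
601.0,2917.23,14166.24
602.0,2665.31,13708.91
603.0,2442.07,13296.88
604.0,2245.34,12922.05
605.0,2072.94,12576.31
606.0,1922.71,12251.54
607.0,1792.47,11939.64
608.0,1680.05,11632.49
609.0,1583.29,11321.98
610.0,1500.00,11000.00
611.0,1426.78,10672.91
612.0,1361.09,10352.34
613.0,1302.03,10038.10
614.0,1248.73,9730.02
615.0,1200.28,9427.89
616.0,1155.82,9131.53
617.0,1114.44,8840.75
618.0,1075.27,8555.36
619.0,1037.42,8275.17
620.0,1000.00,8000.00
621.0,963.38,7721.95
622.0,928.48,7436.62
623.0,895.20,7149.09
624.0,863.44,6864.42
625.0,833.12,6587.66
626.0,804.16,6323.90
627.0,776.46,6078.18
628.0,749.92,5855.58
629.0,724.47,5661.17
630.0,700.00,5500.00
631.0,676.16,5364.00
632.0,652.75,5240.57
633.0,629.92,5128.00
634.0,607.84,5024.57
635.0,586.67,4928.57
636.0,566.56,4838.29
637.0,547.68,4752.00
638.0,530.19,4668.00
639.0,514.24,4584.57
640.0,500.00,4500.00
641.0,487.20,4415.12
642.0,475.38,4332.01
643.0,464.40,4250.82
644.0,454.13,4171.73
645.0,444.44,4094.89
646.0,435.20,4020.46
647.0,426.27,3948.59
648.0,417.51,3879.45
649.0,408.80,3813.20
650.0,400.00,3750.00
651.0,390.85,3689.67
652.0,381.33,3631.77
653.0,371.67,3576.06
654.0,362.11,3522.30
655.0,352.89,3470.24
656.0,344.23,3419.64
657.0,336.38,3370.26
658.0,329.57,3321.85
659.0,324.03,3274.18
660.0,320.00,3227.00
661.0,316.97,3180.68
662.0,314.25,3135.63
663.0,311.82,3091.68
664.0,309.63,3048.65
665.0,307.67,3006.36
666.0,305.89,2964.65
667.0,304.26,2923.33
668.0,302.76,2882.23
669.0,301.35,2841.18
670.0,300.00,2800.00
671.0,298.73,2758.94
672.0,297.57,2718.33
673.0,296.51,2678.08
674.0,295.52,2638.12
675.0,294.58,2598.37
676.0,293.68,2558.75
677.0,292.79,2519.18
678.0,291.89,2479.58
679.0,290.97,2439.88
680.0,290.00,2400.00
681.0,288.91,2358.85
682.0,287.68,2315.90
683.0,286.37,2271.93
684.0,285.04,2227.71
685.0,283.75,2183.99
686.0,282.56,2141.56
687.0,281.53,2101.18
688.0,280.72,2063.61
689.0,280.19,2029.63
690.0,280.00,2000.00
691.0,280.19,1974.00
692.0,280.72,1950.16
693.0,281.53,1928.12
694.0,282.56,1907.51
695.0,283.75,1887.98
696.0,285.04,1869.18
697.0,286.37,1850.74
698.0,287.68,1832.30
699.0,288.91,1813.51
700.0,290.00,1794.00
701.0,291.00,1774.07
702.0,292.00,1754.26
703.0,293.00,1734.57
704.0,294.00,1714.99
705.0,295.00,1695.52
706.0,296.00,1676.18
707.0,297.00,1656.95
708.0,298.00,1637.85
709.0,299.00,1618.86
710.0,300.00,1600.00
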