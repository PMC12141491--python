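wavelength_nm,absorption
640.0,0.047383
641.0,0.056001
642.0,0.065812
643.0,0.076911
644.0,0.089388
645.0,0.103328
646.0,0.118808
647.0,0.135892
648.0,0.154637
649.0,0.175081
650.0,0.197250
651.0,0.221152
652.0,0.246776
653.0,0.274091
654.0,0.303048
655.0,0.333573
656.0,0.365575
657.0,0.398935
658.0,0.433517
659.0,0.469160
660.0,0.505679
661.0,0.542868
662.0,0.580501
663.0,0.618327
664.0,0.656078
665.0,0.693465
666.0,0.730183
667.0,0.765911
668.0,0.800320
669.0,0.833069
670.0,0.863817
671.0,0.892223
672.0,0.917953
673.0,0.940688
674.0,0.960127
675.0,0.975998
676.0,0.988060
677.0,0.996113
678.0,1.000000
679.0,0.999617
680.0,0.994914
681.0,0.985897
682.0,0.972631
683.0,0.955240
684.0,0.933906
685.0,0.908865
686.0,0.880402
687.0,0.848849
688.0,0.814571
689.0,0.777967
690.0,0.739456
691.0,0.699468
692.0,0.658438
693.0,0.616797
694.0,0.574962
695.0,0.533330
696.0,0.492271
697.0,0.452122
698.0,0.413183
699.0,0.375716
700.0,0.339939
701.0,0.306029
702.0,0.274118
703.0,0.244300
704.0,0.216629
705.0,0.191123
706.0,0.167769
707.0,0.146524
708.0,0.127322
709.0,0.110076
710.0,0.094684
711.0,0.081031
712.0,0.068995
713.0,0.058449
714.0,0.049263
715.0,0.041310
716.0,0.034465
717.0,0.028608
718.0,0.023625
719.0,0.019412
720.0,0.015868
721.0,0.012906
722.0,0.010443
723.0,0.008407
724.0,0.006734
725.0,0.005366
726.0,0.004254
727.0,0.003356
728.0,0.002634
729.0,0.002056
730.0,0.001597
731.0,0.001235
732.0,0.000949
733.0,0.000726
734.0,0.000553
735.0,0.000419
736.0,0.000315
737.0,0.000236
738.0,0.000176
739.0,0.000131
740.0,0.000097
741.0,0.000071
742.0,0.000052
743.0,0.000038
744.0,0.000027
745.0,0.000020
746.0,0.000014
747.0,0.000010
748.0,0.000007
749.0,0.000005
750.0,0.000004
751.0,0.000002
752.0,0.000002
753.0,0.000001
754.0,0.000001
755.0,0.000001
756.0,0.000000
757.0,0.000000
758.0,0.000000
759.0,0.000000
760.0,0.000000
761.0,0.000000
762.0,0.000000
763.0,0.000000
764.0,0.000000
765.0,0.000000
766.0,0.000000
767.0,0.000000
768.0,0.000000
769.0,0.000000
770.0,0.000000
771.0,0.000000
772.0,0.000000
773.0,0.000000
774.0,0.000000
775.0,0.000000
776.0,0.000000
777.0,0.000000
778.0,0.000000
779.0,0.000000
780.0,0.000000
781.0,0.000000
782.0,0.000000
783.0,0.000000
784.0,0.000000
785.0,0.000000
786.0,0.000000
787.0,0.000000
788.0,0.000000
789.0,0.000000
790.0,0.000000
791.0,0.000000
792.0,0.000000
793.0,0.000000
794.0,0.000000
795.0,0.000000
796.0,0.000000
797.0,0.000000
798.0,0.000000
799.0,0.000000
800.0,0.000000
801.0,0.000000
802.0,0.000000
803.0,0.000000
804.0,0.000000
805.0,0.000000
806.0,0.000000
807.0,0.000000
808.0,0.000000
809.0,0.000000
810.0,0.000000
811.0,0.000000
812.0,0.000000
813.0,0.000000
814.0,0.000000
815.0,0.000000
816.0,0.000000
817.0,0.000000
818.0,0.000000
819.0,0.000000
820.0,0.000000
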