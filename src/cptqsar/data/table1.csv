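compound,species,lc50_mM
4a,T_cinnabarinus,0.09611
4a,B_xylophilus,0.26150
4a,B_brassicae,0.20589
4b,T_cinnabarinus,0.02384
4b,B_xylophilus,0.16486
4b,B_brassicae,0.05939
4c,T_cinnabarinus,0.00942
4c,B_xylophilus,0.11331
4c,B_brassicae,0.15621
4d,T_cinnabarinus,0.00761
4d,B_xylophilus,0.27035
4d,B_brassicae,0.05943
4e,T_cinnabarinus,0.07299
4e,B_xylophilus,0.24100
4e,B_brassicae,0.35496
4f,T_cinnabarinus,0.09457
4f,B_xylophilus,0.24809
4f,B_brassicae,0.17584
4g,T_cinnabarinus,0.13990
4g,B_xylophilus,0.22729
4g,B_brassicae,0.11500
4h,T_cinnabarinus,0.01156
4h,B_xylophilus,0.24162
4h,B_brassicae,0.08253
4i,T_cinnabarinus,0.01841
4i,B_xylophilus,0.13670
4i,B_brassicae,0.20292
4j,T_cinnabarinus,0.08835
4j,B_xylophilus,0.28470
4j,B_brassicae,0.12832
4k,T_cinnabarinus,0.06152
4k,B_xylophilus,0.09212
4k,B_brassicae,0.15807
4l,T_cinnabarinus,0.08218
4l,B_xylophilus,0.26553
4l,B_brassicae,0.18599
5a,T_cinnabarinus,0.04029
5a,B_xylophilus,0.29812
5a,B_brassicae,0.11830
5b,T_cinnabarinus,0.05929
5b,B_xylophilus,0.07944
5b,B_brassicae,0.20210
5c,T_cinnabarinus,0.08796
5c,B_xylophilus,0.36781
5c,B_brassicae,0.21269
5d,T_cinnabarinus,0.01707
5d,B_xylophilus,0.20740
5d,B_brassicae,0.16198
5e,T_cinnabarinus,0.06648
5e,B_xylophilus,0.12162
5e,B_brassicae,0.10958
5f,T_cinnabarinus,0.16309
5f,B_xylophilus,0.42748
5f,B_brassicae,0.40716
5g,T_cinnabarinus,0.04171
5g,B_xylophilus,0.20948
5g,B_brassicae,0.17947
5h,T_cinnabarinus,0.05408
5h,B_xylophilus,0.18991
5h,B_brassicae,0.15555
5i,T_cinnabarinus,0.05913
5i,B_xylophilus,0.24922
5i,B_brassicae,0.12422
5j,T_cinnabarinus,0.06063
5j,B_xylophilus,0.10277
5j,B_brassicae,0.19429
5k,T_cinnabarinus,0.08516
5k,B_xylophilus,0.11697
5k,B_brassicae,0.15819
5l,T_cinnabarinus,0.02745
5l,B_xylophilus,0.21472
5l,B_brassicae,0.08071
6a,T_cinnabarinus,0.09915
6a,B_xylophilus,0.03649
6a,B_brassicae,0.11815
6b,T_cinnabarinus,0.05079
6b,B_xylophilus,0.32122
6b,B_brassicae,0.11710
6c,T_cinnabarinus,0.03930
6c,B_xylophilus,0.30762
6c,B_brassicae,0.07464
6d,T_cinnabarinus,0.04877
6d,B_xylophilus,0.27567
6d,B_brassicae,0.11019
1,T_cinnabarinus,0.19719
1,B_xylophilus,0.06861
1,B_brassicae,0.14593
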