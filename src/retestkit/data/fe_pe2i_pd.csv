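subject,region,session,value
1,striatum,test,1.763
1,striatum,retest,1.827
2,striatum,test,1.051
2,striatum,retest,1.065
3,striatum,test,1.892
3,striatum,retest,1.91
4,striatum,test,1.835
4,striatum,retest,1.789
5,striatum,test,1.306
5,striatum,retest,1.372
6,striatum,test,1.273
6,striatum,retest,1.497
7,striatum,test,1.339
7,striatum,retest,1.217
8,striatum,test,2.801
8,striatum,retest,2.256
9,striatum,test,1.537
9,striatum,retest,1.426
10,striatum,test,1.978
10,striatum,retest,1.948
1,caudate,test,2.428
1,caudate,retest,2.562
2,caudate,test,0.914
2,caudate,retest,0.91
3,caudate,test,2.339
3,caudate,retest,2.388
4,caudate,test,1.697
4,caudate,retest,1.872
5,caudate,test,1.43
5,caudate,retest,1.496
6,caudate,test,1.876
6,caudate,retest,2.125
7,caudate,test,1.356
7,caudate,retest,1.245
8,caudate,test,3.268
8,caudate,retest,2.588
9,caudate,test,1.928
9,caudate,retest,1.744
10,caudate,test,2.564
10,caudate,retest,2.582
1,putamen,test,1.264
1,putamen,retest,1.275
2,putamen,test,1.095
2,putamen,retest,1.121
3,putamen,test,1.516
3,putamen,retest,1.513
4,putamen,test,1.824
4,putamen,retest,1.607
5,putamen,test,1.15
5,putamen,retest,1.21
6,putamen,test,0.672
6,putamen,retest,0.898
7,putamen,test,1.203
7,putamen,retest,1.104
8,putamen,test,2.332
8,putamen,retest,1.888
9,putamen,test,1.166
9,putamen,retest,1.112
10,putamen,test,1.423
10,putamen,retest,1.37
1,ventral striatum,test,1.736
1,ventral striatum,retest,1.722
2,ventral striatum,test,1.623
2,ventral striatum,retest,1.687
3,ventral striatum,test,2.317
3,ventral striatum,retest,2.319
4,ventral striatum,test,3.131
4,ventral striatum,retest,2.717
5,ventral striatum,test,1.848
5,ventral striatum,retest,2.021
6,ventral striatum,test,1.758
6,ventral striatum,retest,1.838
7,ventral striatum,test,2.441
7,ventral striatum,retest,2.011
8,ventral striatum,test,3.054
8,ventral striatum,retest,2.714
9,ventral striatum,test,2.211
9,ventral striatum,retest,2.191
10,ventral striatum,test,2.855
10,ventral striatum,retest,2.686
1,substantia nigra,test,0.73
1,substantia nigra,retest,0.849
2,substantia nigra,test,0.635
2,substantia nigra,retest,0.602
3,substantia nigra,test,0.813
3,substantia nigra,retest,0.798
4,substantia nigra,test,1.016
4,substantia nigra,retest,0.854
5,substantia nigra,test,0.668
5,substantia nigra,retest,0.666
6,substantia nigra,test,0.397
6,substantia nigra,retest,0.602
7,substantia nigra,test,0.752
7,substantia nigra,retest,0.754
8,substantia nigra,test,0.894
8,substantia nigra,retest,0.716
9,substantia nigra,test,0.653
9,substantia nigra,retest,0.603
10,substantia nigra,test,0.796
10,substantia nigra,retest,0.75
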