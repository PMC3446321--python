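strain	role	batch	replicate	day	viability
strain01	tested	1	1	0.3	1.153733236076319
strain01	tested	1	2	0.3	0.8154602067165143
strain01	tested	1	3	0.3	0.850836631559092
strain01	tested	1	1	2.0	0.812679815776464
strain01	tested	1	2	2.0	1.0120763701386843
strain01	tested	1	3	2.0	0.8930130123228613
strain01	tested	1	1	7.0	3.434015394530849
strain01	tested	1	2	7.0	2.043958078094364
strain01	tested	1	3	7.0	4.045733532667574
strain01	tested	1	1	14.0	0.5481382893925584
strain01	tested	1	2	14.0	0.6402698516590485
strain01	tested	1	3	14.0	0.5437560850594808
strain02	tested	2	1	0.3	0.95580106839028
strain02	tested	2	2	0.3	1.1311516466819265
strain02	tested	2	3	0.3	1.2159393964778662
strain02	tested	2	1	2.0	0.9901570265389835
strain02	tested	2	2	2.0	1.0000570042838128
strain02	tested	2	3	2.0	1.1826455973588685
strain02	tested	2	1	7.0	0.7093161869482284
strain02	tested	2	2	7.0	0.6235898225727343
strain02	tested	2	3	7.0	0.9135753797285149
strain02	tested	2	1	14.0	0.5579427466893471
strain02	tested	2	2	14.0	0.43454582245115986
strain02	tested	2	3	14.0	0.5421587116875295
strain03	tested	1	1	0.3	0.8224556237291097
strain03	tested	1	2	0.3	0.7113563818809672
strain03	tested	1	3	0.3	0.6700291797062431
strain03	tested	1	1	2.0	0.909724317161444
strain03	tested	1	2	2.0	1.0805915389191467
strain03	tested	1	3	2.0	0.8619416909425096
strain03	tested	1	1	7.0	0.637207172434912
strain03	tested	1	2	7.0	0.7985621529828795
strain03	tested	1	3	7.0	0.8534280182088397
strain03	tested	1	1	14.0	0.5262687008130171
strain03	tested	1	2	14.0	0.6231252872094111
strain03	tested	1	3	14.0	0.6884131286214382
wt1	wildtype	1	1	0.3	0.8664658983957828
wt1	wildtype	1	2	0.3	0.7674788573485494
wt1	wildtype	1	3	0.3	0.9681084922363004
wt1	wildtype	1	1	2.0	0.9489187592386004
wt1	wildtype	1	2	2.0	1.1250430648049747
wt1	wildtype	1	3	2.0	0.6984739503414495
wt1	wildtype	1	1	7.0	0.6477413425787438
wt1	wildtype	1	2	7.0	0.6252681813768549
wt1	wildtype	1	3	7.0	0.522701769386497
wt1	wildtype	1	1	14.0	0.5731233425697718
wt1	wildtype	1	2	14.0	0.6210272007777746
wt1	wildtype	1	3	14.0	0.4820539483161477
wt1	wildtype	2	1	0.3	1.360352222395887
wt1	wildtype	2	2	0.3	1.2153098996439904
wt1	wildtype	2	3	0.3	1.1689308576241029
wt1	wildtype	2	1	2.0	1.1173453589322815
wt1	wildtype	2	2	2.0	1.2482569663333207
wt1	wildtype	2	3	2.0	0.7899530785421268
wt1	wildtype	2	1	7.0	0.9544692711684284
wt1	wildtype	2	2	7.0	0.9523426381509879
wt1	wildtype	2	3	7.0	0.5927814622155568
wt1	wildtype	2	1	14.0	0.683875263553298
wt1	wildtype	2	2	14.0	0.6068521873710653
wt1	wildtype	2	3	14.0	0.7459615494384084
ctrl1	negative_control	1	1	0.3	0.8271628585346873
ctrl1	negative_control	1	2	0.3	0.899794018250924
ctrl1	negative_control	1	3	0.3	0.9671797317747739
ctrl1	negative_control	1	1	2.0	0.7579077696386424
ctrl1	negative_control	1	2	2.0	1.0179370616272712
ctrl1	negative_control	1	3	2.0	0.8843221349809297
ctrl1	negative_control	1	1	7.0	0.8159153116092261
ctrl1	negative_control	1	2	7.0	0.6661044824438681
ctrl1	negative_control	1	3	7.0	0.9187870246971256
ctrl1	negative_control	1	1	14.0	0.6307152139704703
ctrl1	negative_control	1	2	14.0	0.5392660428379653
ctrl1	negative_control	1	3	14.0	0.6340992395638718
ctrl1	negative_control	2	1	0.3	1.3265283556323784
ctrl1	negative_control	2	2	0.3	1.475282270144968
ctrl1	negative_control	2	3	0.3	0.7526905922321878
ctrl1	negative_control	2	1	2.0	1.2302785420495486
ctrl1	negative_control	2	2	2.0	1.1315947716020327
ctrl1	negative_control	2	3	2.0	1.0119124773931802
ctrl1	negative_control	2	1	7.0	0.6902380446626675
ctrl1	negative_control	2	2	7.0	1.085512212737841
ctrl1	negative_control	2	3	7.0	0.6559089074230033
ctrl1	negative_control	2	1	14.0	0.7146254866012782
ctrl1	negative_control	2	2	14.0	0.8277764388966962
ctrl1	negative_control	2	3	14.0	0.46332820068871333
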