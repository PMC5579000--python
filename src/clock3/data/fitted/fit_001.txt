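# fitted clock rate set (reduced-scale SRES run, verified
# against the 16-condition registry at dt=0.005, 600 h)
# name	value	range_low	range_high
ab	5.594664177372952	2.797332088686476	8.391996266059428
abc	6.242035401138024	3.121017700569012	9.363053101707035
abro	12.272930884381067	6.136465442190533	18.4093963265716
abrt	4.768952929848132	2.384476464924066	7.153429394772198
abth	0.5029395793632775	0.2797332088686476	83.91996266059428
ac	5.9015165012021775	2.9507582506010888	8.852274751803266
accl	0.712178853450551	0.3560894267252755	1.0682682801758265
acth	4.393122305932357	0.2950758250601089	88.52274751803266
ag	1.1637819666360414	0.5818909833180207	1.745672949954062
agb	0.6564323125411671	0.32821615627058354	0.9846484688117506
agr	0.65634099037904	0.32817049518952	0.98451148556856
an	21.15863917035786	0.2950758250601089	88.52274751803266
arco	5.794544322869293	2.8972721614346466	8.69181648430394
arct	6.630942059931802	3.315471029965901	9.946413089897703
arcth	2.2899977669234213	0.28972721614346464	86.9181648430394
dab	0.30211153293117204	0.15105576646558602	0.45316729939675804
dabth	1.5059375185628552	0.015105576646558603	4.531672993967581
dbc	1.01922834760917	0.509614173804585	1.5288425214137549
dbro	0.027739315115627584	0.013869657557813792	0.04160897267344138
dbrt	0.3928256306815531	0.19641281534077654	0.5892384460223297
dc	1.0566890646512397	0.5283445323256198	1.5850335969768596
dccl	0.6999123500449468	0.3499561750224734	1.0498685250674202
dcth	0.32118950950754527	0.05283445323256199	15.850335969768597
dg	1.3008921225781107	0.6504460612890554	1.9513381838671662
dgb	0.6945492947545152	0.3472746473772576	1.0418239421317728
dgr	0.6361301494104143	0.3180650747052072	0.9541952241156215
dn	0.027959467537213158	0.027959467537213158	15.850335969768597
drco	0.24342348639009265	0.12171174319504632	0.365135229585139
drct	0.42151714558960585	0.21075857279480292	0.6322757183844088
drcth	0.07443218618434115	0.012171174319504633	3.6513522958513898
exb	0.6983823050972675	0.34919115254863375	1.0475734576459013
excl	0.6913502344762035	0.34567511723810174	1.037025351714305
exco	0.5845416182032643	0.29227080910163217	0.8768124273048965
excr	0.267804690238422	0.133902345119211	0.401707035357633
exct	0.5335896083439465	0.26679480417197327	0.8003844125159199
exk	0.16395657850296375	0.08197828925148187	0.24593486775444562
expo	0.6892241591083309	0.34461207955416545	1.0338362386624964
expp	0.11503841728479224	0.05751920864239612	0.17255762592718835
expt	0.6912913284196861	0.34564566420984305	1.036936992629529
expth	1.4285871183465773	0.034461207955416545	10.338362386624965
exrev	0.7089383943971682	0.3544691971985841	1.0634075915957524
ga	6.845979100008799	3.4229895500043996	10.2689686500132
gar1	1.3979680019498393	0.6989840009749196	2.096952002924759
gar2	5.354371311084878	2.677185655542439	8.031556966627317
gd	0.3385793632532454	0.1692896816266227	0.5078690448798681
gdr1	0.06545553490057382	0.03272776745028691	0.09818330235086073
gdr2	0.5009653825609419	0.25048269128047096	0.7514480738414129
gdrev	0.5699316168230203	0.28496580841151015	0.8548974252345305
grev	12.752811930660313	6.376405965330156	19.129217895990468
hob	0.24669890170202743	0.12334945085101372	0.37004835255304114
hocl	0.23811607758129266	0.11905803879064633	0.35717411637193897
hoo	0.18028935924871015	0.09014467962435507	0.2704340388730652
hor	0.26311149608537215	0.13155574804268608	0.3946672441280582
hot	0.1673983451781734	0.0836991725890867	0.2510975177672601
hoth	2.315340342027101	0.009014467962435508	2.7043403887306523
inb	0.40603130916904495	0.20301565458452248	0.6090469637535674
inbc	0.4562053386848008	0.2281026693424004	0.6843080080272012
incl	0.2972790556642566	0.1486395278321283	0.4459185834963849
incr	0.26698204225505845	0.13349102112752922	0.4004730633825877
ink	0.6379727931065106	0.3189863965532553	0.9569591896597658
inp	0.5830877046174476	0.2915438523087238	0.8746315569261714
inrev	0.5912746357468377	0.29563731787341885	0.8869119536202565
tlb	1.1279754164077531	0.5639877082038766	1.6919631246116298
tlcl	1.0098465243931931	0.5049232621965966	1.5147697865897896
tlco	1.8794606549557262	0.9397303274778631	2.8191909824335895
tlct	3.0419407377226784	1.5209703688613392	4.562911106584018
tlpo	2.3016437144036077	1.1508218572018039	3.4524655716054116
tlpt	0.5544502988225263	0.27722514941126314	0.8316754482337894
tlpth	1.665514769307187	0.11508218572018039	34.52465571605411
tlrev	1.1609559984425213	0.5804779992212606	1.741433997663782
trb	1.024843594398734	0.512421797199367	1.537265391598101
trcl	0.3409491489790537	0.17047457448952685	0.5114237234685806
trco	2.1037495982437413	1.0518747991218707	3.155624397365612
trct	2.3912915607681486	1.1956457803840743	3.5869373411522227
trpo	1.6975119234007738	0.8487559617003869	2.5462678851011606
trpt	1.093415241076465	0.5467076205382325	1.6401228616146977
trpth	1.5435082399231588	0.08487559617003869	25.462678851011606
trrev	1.1558391730444353	0.5779195865222176	1.733758759566653
ub	1.1885258872945803	0.5942629436472902	1.7827888309418705
ucl	0.5776552451601922	0.2888276225800961	0.8664828677402883
umb	0.416052662416305	0.2080263312081525	0.6240789936244575
umcl	0.4073761314339141	0.20368806571695705	0.6110641971508711
umco	0.2291993289346842	0.1145996644673421	0.3437989934020263
umct	0.15035320557022674	0.07517660278511337	0.22552980835534012
umpo	0.32762534021741363	0.16381267010870681	0.49143801032612044
umpt	0.3866728131884741	0.19333640659423704	0.5800092197827111
umpth	0.11694539987069077	0.01638126701087068	4.9143801032612044
umrev	0.46375600852982923	0.23187800426491462	0.6956340127947438
upb	2.0740684915599004	1.0370342457799502	3.1111027373398503
upcl	1.4019476039114174	0.7009738019557087	2.102921405867126
uppo	1.6735952040996238	0.8367976020498119	2.5103928061494356
uppt	2.001244881748803	1.0006224408744016	3.0018673226232044
uppth	10.272156169112902	0.08367976020498119	25.103928061494358
uprev	2.595286605925313	1.2976433029626564	3.892929908887969
upth	0.913799315008013	0.03901030471409934	11.7030914142298
upuo	0.7802060942819867	0.39010304714099336	1.17030914142298
uput	0.1979184392963848	0.0989592196481924	0.2968776589445772
urev	1.3764961079841609	0.6882480539920804	2.0647441619762414
uro	0.0703555380391055	0.03517776901955275	0.10553330705865827
urt	0.1599756858890102	0.0799878429445051	0.2399635288335153
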