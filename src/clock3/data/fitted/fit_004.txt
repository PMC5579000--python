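# fitted clock rate set (reduced-scale SRES run, verified
# against the 16-condition registry at dt=0.005, 600 h)
# name	value	range_low	range_high
ab	5.564521312793014	2.782260656396507	8.346781969189522
abc	6.197736237542734	3.098868118771367	9.2966043563141
abro	12.91485076186977	6.457425380934885	19.372276142804655
abrt	4.706875466361896	2.353437733180948	7.060313199542843
abth	0.5067891024658046	0.2782260656396507	83.46781969189522
ac	5.889157307235118	2.944578653617559	8.833735960852678
accl	0.707604650294773	0.3538023251473865	1.0614069754421596
acth	4.439188662463977	0.2944578653617559	88.33735960852678
ag	1.1836788155623332	0.5918394077811666	1.7755182233434998
agb	0.6395484966767803	0.31977424833839013	0.9593227450151705
agr	0.6472763432448255	0.32363817162241276	0.9709145148672382
an	20.902426251493495	0.2944578653617559	88.33735960852678
arco	5.698163491477997	2.8490817457389985	8.547245237216995
arct	6.78678599620996	3.39339299810498	10.18017899431494
arcth	2.298261775823587	0.28490817457389983	85.47245237216995
dab	0.29929989302534155	0.14964994651267077	0.4489498395380123
dabth	1.4392717202304999	0.014964994651267077	4.4894983953801235
dbc	0.994235327575939	0.4971176637879695	1.4913529913639085
dbro	0.028043320641073753	0.014021660320536877	0.042064980961610626
dbrt	0.3850962948915289	0.19254814744576446	0.5776444423372934
dc	1.0582166041171468	0.5291083020585734	1.5873249061757202
dccl	0.7159347604609921	0.35796738023049607	1.0739021406914881
dcth	0.3247395898001174	0.05291083020585734	15.873249061757202
dg	1.310261192774166	0.655130596387083	1.9653917891612491
dgb	0.6895853815309573	0.34479269076547864	1.034378072296436
dgr	0.6240192579584815	0.3120096289792407	0.9360288869377222
dn	0.027952076692463364	0.027952076692463364	15.873249061757202
drco	0.24014564503706665	0.12007282251853332	0.36021846755559994
drct	0.4264832257104659	0.21324161285523294	0.6397248385656988
drcth	0.07650753094412034	0.012007282251853333	3.6021846755559994
exb	0.6942217806224237	0.34711089031121184	1.0413326709336355
excl	0.6700663821314595	0.33503319106572976	1.0050995731971892
exco	0.5834256714818598	0.2917128357409299	0.8751385072227896
excr	0.2589075987556136	0.1294537993778068	0.3883613981334204
exct	0.54237138644617	0.271185693223085	0.8135570796692551
exk	0.16063123001574242	0.08031561500787121	0.24094684502361363
expo	0.6737976840314011	0.33689884201570053	1.0106965260471017
expp	0.11347223112310581	0.056736115561552905	0.17020834668465873
expt	0.680098812609638	0.340049406304819	1.020148218914457
expth	1.3397513109020878	0.033689884201570056	10.106965260471018
exrev	0.7338832241530557	0.36694161207652787	1.1008248362295836
ga	6.849493970425707	3.4247469852128534	10.274240955638561
gar1	1.4154250815071616	0.7077125407535808	2.1231376222607423
gar2	5.304867929476247	2.6524339647381234	7.95730189421437
gd	0.34161817354454654	0.17080908677227327	0.5124272603168198
gdr1	0.06658921356757735	0.03329460678378868	0.09988382035136603
gdr2	0.4962865642624425	0.24814328213122125	0.7444298463936637
gdrev	0.5660330135463272	0.2830165067731636	0.8490495203194908
grev	12.714324252149046	6.357162126074523	19.071486378223568
hob	0.24226301651063123	0.12113150825531561	0.36339452476594686
hocl	0.24141287550522184	0.12070643775261092	0.36211931325783275
hoo	0.17935491520906527	0.08967745760453263	0.26903237281359793
hor	0.26407062504619416	0.13203531252309708	0.39610593756929124
hot	0.17011379814292965	0.08505689907146483	0.25517069721439445
hoth	2.3109199167836985	0.008967745760453264	2.6903237281359793
inb	0.4015904513228962	0.2007952256614481	0.6023856769843443
inbc	0.44373192540823914	0.22186596270411957	0.6655978881123588
incl	0.30049023326726904	0.15024511663363452	0.4507353499009036
incr	0.26345661268105247	0.13172830634052624	0.3951849190215787
ink	0.6302480267084047	0.31512401335420237	0.9453720400626071
inp	0.5947122524545568	0.2973561262272784	0.8920683786818353
inrev	0.6090799331578667	0.30453996657893334	0.9136198997368
tlb	1.103017815063766	0.551508907531883	1.6545267225956488
tlcl	0.9935762892022787	0.49678814460113935	1.490364433803418
tlco	1.9174266489856528	0.9587133244928264	2.8761399734784794
tlct	3.101202659902717	1.5506013299513586	4.651803989854075
tlpo	2.2266902854565713	1.1133451427282857	3.3400354281848568
tlpt	0.5561951063981545	0.27809755319907725	0.8342926595972318
tlpth	1.4924146417298112	0.11133451427282856	33.400354281848564
tlrev	1.1873076447545543	0.5936538223772772	1.7809614671318315
trb	1.0153622780914862	0.5076811390457431	1.5230434171372291
trcl	0.3348040225101419	0.16740201125507095	0.5022060337652129
trco	2.185262614624416	1.092631307312208	3.277893921936624
trct	2.3681065077813863	1.1840532538906932	3.5521597616720797
trpo	1.7248505161107164	0.8624252580553582	2.5872757741660743
trpt	1.063020692282769	0.5315103461413845	1.5945310384241536
trpth	1.7570850126503093	0.08624252580553582	25.87275774166074
trrev	1.1196208058728294	0.5598104029364147	1.6794312088092442
ub	1.2345431867445606	0.6172715933722803	1.851814780116841
ucl	0.5847247659173093	0.29236238295865463	0.877087148875964
umb	0.4180858474727869	0.20904292373639344	0.6271287712091803
umcl	0.39686035802151015	0.19843017901075508	0.5952905370322652
umco	0.22804671695480208	0.11402335847740104	0.34207007543220314
umct	0.1470522674666172	0.0735261337333086	0.2205784011999258
umpo	0.3235935269039621	0.16179676345198105	0.48539029035594317
umpt	0.3832972513410216	0.1916486256705108	0.5749458770115324
umpth	0.1146387575738059	0.016179676345198103	4.853902903559431
umrev	0.4740786333284558	0.2370393166642279	0.7111179499926836
upb	2.0620024200717153	1.0310012100358577	3.0930036301075727
upcl	1.3979866037958628	0.6989933018979314	2.0969799056937943
uppo	1.6442227654602237	0.8221113827301119	2.4663341481903354
uppt	2.019547938292061	1.0097739691460306	3.0293219074380917
uppth	10.44798254263535	0.08221113827301119	24.663341481903352
uprev	2.636231939113741	1.3181159695568705	3.9543479086706115
upth	0.9090952570808051	0.0388483418888441	11.654502566653228
upuo	0.7769668377768819	0.38848341888844096	1.1654502566653229
uput	0.19862835282132246	0.09931417641066123	0.2979425292319837
urev	1.346888318069898	0.673444159034949	2.020332477104847
uro	0.06997157048330326	0.03498578524165163	0.10495735572495488
urt	0.16317344959432287	0.08158672479716143	0.2447601743914843
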