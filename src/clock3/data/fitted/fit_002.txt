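# fitted clock rate set (reduced-scale SRES run, verified
# against the 16-condition registry at dt=0.005, 600 h)
# name	value	range_low	range_high
ab	5.620846448469798	2.810423224234899	8.431269672704698
abc	6.44031905064275	3.220159525321375	9.660478575964126
abro	12.498233386147906	6.249116693073953	18.74735007922186
abrt	4.854786775907493	2.4273933879537464	7.28218016386124
abth	0.4893025288255006	0.2810423224234899	84.31269672704698
ac	6.113017399007761	3.0565086995038806	9.169526098511643
accl	0.6933999807850849	0.34669999039254246	1.0400999711776273
acth	4.509348880761885	0.30565086995038804	91.69526098511642
ag	1.1898588390749056	0.5949294195374528	1.7847882586123585
agb	0.6391922268745339	0.31959611343726696	0.9587883403118009
agr	0.6531966254887468	0.3265983127443734	0.9797949382331201
an	22.03195991057692	0.30565086995038804	91.69526098511642
arco	5.855734520627127	2.9278672603135636	8.78360178094069
arct	6.522611352213257	3.2613056761066286	9.783917028319886
arcth	2.2473211772325397	0.29278672603135636	87.83601780940691
dab	0.30659084842767387	0.15329542421383693	0.45988627264151083
dabth	1.3764987410639782	0.015329542421383693	4.598862726415108
dbc	1.0105641817667987	0.5052820908833994	1.5158462726501982
dbro	0.028022644417834554	0.014011322208917277	0.04203396662675183
dbrt	0.4076639534367478	0.2038319767183739	0.6114959301551217
dc	1.080066162554586	0.540033081277293	1.6200992438318789
dccl	0.6742238570088731	0.33711192850443655	1.0113357855133096
dcth	0.3187917451206878	0.0540033081277293	16.20099243831879
dg	1.324668965234104	0.662334482617052	1.9870034478511558
dgb	0.6794216577788584	0.3397108288894292	1.0191324866682876
dgr	0.6278135858823488	0.3139067929411744	0.9417203788235232
dn	0.02720033794573913	0.02720033794573913	16.20099243831879
drco	0.24945151405542793	0.12472575702771396	0.3741772710831419
drct	0.42762527361700464	0.21381263680850232	0.641437910425507
drcth	0.08006235346920353	0.012472575702771396	3.741772710831419
exb	0.6816432612526298	0.3408216306263149	1.0224648918789447
excl	0.6994557311777023	0.34972786558885116	1.0491835967665535
exco	0.5907764986544406	0.2953882493272203	0.8861647479816609
excr	0.258097961987523	0.1290489809937615	0.3871469429812845
exct	0.558918949879527	0.2794594749397635	0.8383784248192905
exk	0.16665352933599684	0.08332676466799842	0.24998029400399524
expo	0.6725040207320175	0.33625201036600877	1.0087560310980264
expp	0.11405803309238846	0.05702901654619423	0.17108704963858268
expt	0.6853149447618316	0.3426574723809158	1.0279724171427476
expth	1.403179383825984	0.033625201036600876	10.087560310980264
exrev	0.7207213476695509	0.36036067383477544	1.0810820215043262
ga	6.9531113693971065	3.4765556846985533	10.42966705409566
gar1	1.3967992471281645	0.6983996235640823	2.0951988706922466
gar2	5.430294746883911	2.7151473734419556	8.145442120325868
gd	0.34817156291638923	0.17408578145819462	0.5222573443745838
gdr1	0.0661351684596665	0.03306758422983325	0.09920275268949974
gdr2	0.5099004423146803	0.2549502211573402	0.7648506634720205
gdrev	0.5707455118578327	0.28537275592891637	0.8561182677867492
grev	12.365982535329039	6.182991267664519	18.548973802993558
hob	0.23926573124231715	0.11963286562115857	0.3588985968634757
hocl	0.24192157093794947	0.12096078546897474	0.36288235640692423
hoo	0.1754349048360493	0.08771745241802464	0.26315235725407393
hor	0.257790383690353	0.1288951918451765	0.3866855755355295
hot	0.17092005512862737	0.08546002756431369	0.25638008269294105
hoth	2.3641590266185473	0.008771745241802464	2.6315235725407393
inb	0.4083115314514853	0.20415576572574265	0.6124672971772279
inbc	0.4599957322411627	0.22999786612058135	0.689993598361744
incl	0.30999380311783253	0.15499690155891627	0.4649907046767488
incr	0.25517803103918973	0.12758901551959487	0.3827670465587846
ink	0.6591490953492775	0.32957454767463873	0.9887236430239161
inp	0.5932205742201172	0.2966102871100586	0.8898308613301757
inrev	0.6015202861802129	0.30076014309010646	0.9022804292703194
tlb	1.1547407938492076	0.5773703969246038	1.7321111907738114
tlcl	0.9904319744454884	0.4952159872227442	1.4856479616682325
tlco	1.9306934947729282	0.9653467473864641	2.8960402421593923
tlct	3.012703006680232	1.506351503340116	4.519054510020348
tlpo	2.2580517201160273	1.1290258600580136	3.387077580174041
tlpt	0.5607629347578541	0.28038146737892705	0.8411444021367811
tlpth	1.5884584204399341	0.11290258600580136	33.87077580174041
tlrev	1.226845338863061	0.6134226694315305	1.8402680082945913
trb	1.0511479521915317	0.5255739760957658	1.5767219282872975
trcl	0.3430504283655787	0.17152521418278935	0.5145756425483681
trco	2.0923671956936487	1.0461835978468244	3.138550793540473
trct	2.397060372785415	1.1985301863927076	3.595590559178123
trpo	1.6876386924314242	0.8438193462157121	2.5314580386471364
trpt	1.1158057071928558	0.5579028535964279	1.6737085607892837
trpth	1.638629199940414	0.0843819346215712	25.314580386471363
trrev	1.0998667673872653	0.5499333836936326	1.649800151080898
ub	1.2103272484176515	0.6051636242088257	1.8154908726264773
ucl	0.5748946614976365	0.28744733074881823	0.8623419922464547
umb	0.4155530627715865	0.20777653138579324	0.6233295941573798
umcl	0.4062992539024848	0.2031496269512424	0.6094488808537272
umco	0.2268307049656194	0.1134153524828097	0.3402460574484291
umct	0.1490368028573629	0.07451840142868145	0.22355520428604436
umpo	0.3236234383649448	0.1618117191824724	0.4854351575474172
umpt	0.388687027067624	0.194343513533812	0.583030540601436
umpth	0.11685385736366882	0.01618117191824724	4.854351575474172
umrev	0.4691924017813089	0.23459620089065444	0.7037886026719633
upb	2.0467471345945305	1.0233735672972653	3.0701207018917955
upcl	1.4396805829761796	0.7198402914880898	2.1595208744642695
uppo	1.6444673604018045	0.8222336802009023	2.4667010406027066
uppt	2.087459543155789	1.0437297715778946	3.1311893147336836
uppth	10.589649230392705	0.08222336802009023	24.667010406027067
uprev	2.6691906500384652	1.3345953250192326	4.003785975057697
upth	0.8711549032410674	0.039052684763466954	11.715805429040087
upuo	0.7810536952693391	0.39052684763466955	1.1715805429040087
uput	0.19964433987528737	0.09982216993764369	0.29946650981293105
urev	1.3936242249153745	0.6968121124576873	2.090436337373062
uro	0.06811723402043797	0.034058617010218985	0.10217585103065696
urt	0.16165743466928756	0.08082871733464378	0.24248615200393134
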