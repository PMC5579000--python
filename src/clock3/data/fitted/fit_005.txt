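# fitted clock rate set (reduced-scale SRES run, verified
# against the 16-condition registry at dt=0.005, 600 h)
# name	value	range_low	range_high
ab	5.535930088576405	2.7679650442882027	8.303895132864607
abc	6.060261008621209	3.0301305043106046	9.090391512931813
abro	12.074925154247682	6.037462577123841	18.112387731371523
abrt	4.633155266594755	2.3165776332973773	6.9497328998921315
abth	0.5275519883412488	0.27679650442882026	83.03895132864608
ac	5.720264770503275	2.8601323852516374	8.580397155754913
accl	0.6727332440024177	0.33636662200120887	1.0090998660036266
acth	4.311088341353787	0.28601323852516375	85.80397155754912
ag	1.1260554071611215	0.5630277035805608	1.6890831107416822
agb	0.6656890927381323	0.33284454636906613	0.9985336391071984
agr	0.665982123870483	0.3329910619352415	0.9989731858057245
an	21.41524778686834	0.28601323852516375	85.80397155754912
arco	5.730318272331796	2.865159136165898	8.595477408497693
arct	6.451330216243929	3.2256651081219645	9.676995324365894
arcth	2.370739859450424	0.2865159136165898	85.95477408497693
dab	0.2891284663784211	0.14456423318921055	0.4336926995676317
dabth	1.6143191738842462	0.014456423318921056	4.336926995676317
dbc	1.0510639945129077	0.5255319972564538	1.5765959917693615
dbro	0.027536019157663887	0.013768009578831944	0.04130402873649583
dbrt	0.38223375282047545	0.19111687641023772	0.5733506292307131
dc	1.0518331225663793	0.5259165612831896	1.5777496838495688
dccl	0.6947477057948591	0.34737385289742956	1.0421215586922887
dcth	0.321076305332808	0.05259165612831897	15.777496838495688
dg	1.263303611600525	0.6316518058002625	1.8949554174007874
dgb	0.6798364967816197	0.33991824839080986	1.0197547451724296
dgr	0.6203686866502839	0.31018434332514194	0.9305530299754259
dn	0.025912337917995684	0.025912337917995684	15.777496838495688
drco	0.24112412639367214	0.12056206319683607	0.36168618959050824
drct	0.4126376566359042	0.2063188283179521	0.6189564849538562
drcth	0.07903315085134159	0.012056206319683608	3.6168618959050827
exb	0.7018642906635785	0.35093214533178924	1.0527964359953677
excl	0.6722439252851529	0.33612196264257643	1.0083658879277293
exco	0.5664690125667009	0.28323450628335045	0.8497035188500514
excr	0.2666350918423013	0.13331754592115064	0.3999526377634519
exct	0.5424604560520542	0.2712302280260271	0.8136906840780813
exk	0.15484238929389313	0.07742119464694656	0.23226358394083968
expo	0.6931276062747661	0.34656380313738305	1.0396914094121492
expp	0.11552906590031355	0.05776453295015677	0.17329359885047033
expt	0.6831621574280249	0.34158107871401244	1.0247432361420374
expth	1.4593685969782904	0.03465638031373831	10.396914094121492
exrev	0.6837471280811858	0.3418735640405929	1.0256206921217785
ga	6.439010707888421	3.2195053539442107	9.658516061832632
gar1	1.397691886686517	0.6988459433432584	2.0965378300297752
gar2	5.305322279444824	2.652661139722412	7.9579834191672365
gd	0.3254860784997237	0.16274303924986186	0.48822911774958555
gdr1	0.06441376560329937	0.03220688280164968	0.09662064840494905
gdr2	0.4783617578414793	0.23918087892073964	0.7175426367622189
gdrev	0.5684446414732292	0.2842223207366146	0.8526669622098437
grev	12.973364313339003	6.486682156669501	19.460046470008503
hob	0.23610849975711168	0.11805424987855584	0.3541627496356675
hocl	0.23333129337901307	0.11666564668950653	0.3499969400685196
hoo	0.17761913005432414	0.08880956502716207	0.2664286950814862
hor	0.2559832088854938	0.1279916044427469	0.3839748133282407
hot	0.16794581976490783	0.08397290988245391	0.2519187296473617
hoth	2.3519956817362044	0.008880956502716208	2.664286950814862
inb	0.39076426089274274	0.19538213044637137	0.5861463913391141
inbc	0.44405949641763587	0.22202974820881793	0.6660892446264538
incl	0.28726458631922336	0.14363229315961168	0.43089687947883504
incr	0.2613228561674757	0.13066142808373785	0.39198428425121357
ink	0.6244941627186325	0.3122470813593162	0.9367412440779487
inp	0.5583003018997753	0.27915015094988765	0.8374504528496629
inrev	0.5796617038242533	0.28983085191212665	0.86949255573638
tlb	1.1063932164369523	0.5531966082184762	1.6595898246554284
tlcl	0.975108031523553	0.4875540157617765	1.4626620472853293
tlco	1.8435270169293345	0.9217635084646673	2.765290525394002
tlct	2.9647989140114075	1.4823994570057037	4.4471983710171115
tlpo	2.204989555099484	1.102494777549742	3.307484332649226
tlpt	0.5390188666822866	0.2695094333411433	0.8085283000234299
tlpth	1.6455672943083957	0.1102494777549742	33.07484332649226
tlrev	1.1578153758872924	0.5789076879436462	1.7367230638309388
trb	1.0308415364189256	0.5154207682094628	1.5462623046283883
trcl	0.33731209251571853	0.16865604625785927	0.5059681387735778
trco	2.0694313474595614	1.0347156737297807	3.104147021189342
trct	2.3169005927398345	1.1584502963699173	3.4753508891097518
trpo	1.7057522993558136	0.8528761496779068	2.5586284490337206
trpt	1.0744779797008117	0.5372389898504059	1.6117169695512175
trpth	1.4951085052938984	0.08528761496779068	25.586284490337206
trrev	1.1135709740464295	0.5567854870232147	1.6703564610696442
ub	1.1912832153262718	0.5956416076631359	1.7869248229894077
ucl	0.5899413832936539	0.29497069164682693	0.8849120749404809
umb	0.4063971444758378	0.2031985722379189	0.6095957167137567
umcl	0.40471134635317985	0.20235567317658992	0.6070670195297698
umco	0.22951527233495134	0.11475763616747567	0.344272908502427
umct	0.14734288342884863	0.07367144171442432	0.22101432514327296
umpo	0.31785287815046287	0.15892643907523143	0.47677931722569433
umpt	0.3747540748155629	0.18737703740778144	0.5621311122233443
umpth	0.11426136537047157	0.015892643907523145	4.767793172256943
umrev	0.4603470407810638	0.2301735203905319	0.6905205611715957
upb	2.023797864182349	1.0118989320911744	3.0356967962735233
upcl	1.321177019684233	0.6605885098421165	1.9817655295263494
uppo	1.6418054787228316	0.8209027393614158	2.4627082180842472
uppt	1.970441329576832	0.985220664788416	2.955661994365248
uppth	10.00506560088883	0.08209027393614157	24.62708218084247
uprev	2.4574055066768863	1.2287027533384431	3.686108260015329
upth	0.9486003212139401	0.03793324432058345	11.379973296175034
upuo	0.758664886411669	0.3793324432058345	1.1379973296175034
uput	0.2003741209069412	0.1001870604534706	0.3005611813604118
urev	1.3689049675066596	0.6844524837533298	2.0533574512599895
uro	0.06961042331243836	0.03480521165621918	0.10441563496865754
urt	0.16366884319468095	0.08183442159734047	0.24550326479202142
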