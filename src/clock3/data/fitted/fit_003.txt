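# fitted clock rate set (reduced-scale SRES run, verified
# against the 16-condition registry at dt=0.005, 600 h)
# name	value	range_low	range_high
ab	5.686145296455231	2.8430726482276154	8.529217944682847
abc	6.336557820018131	3.1682789100090654	9.504836730027197
abro	12.48881585617557	6.244407928087785	18.733223784263355
abrt	4.69119380492096	2.34559690246048	7.03679070738144
abth	0.512116858029921	0.28430726482276153	85.29217944682847
ac	5.794363428907485	2.8971817144537426	8.691545143361228
accl	0.7391462603187661	0.36957313015938303	1.1087193904781492
acth	4.594867209831778	0.28971817144537426	86.91545143361228
ag	1.1479570337027476	0.5739785168513738	1.7219355505541214
agb	0.6402645241151561	0.32013226205757805	0.9603967861727342
agr	0.623457696041297	0.3117288480206485	0.9351865440619455
an	19.677389610124152	0.28971817144537426	86.91545143361228
arco	5.978983232818987	2.9894916164094933	8.96847484922848
arct	6.456923500091381	3.2284617500456907	9.685385250137072
arcth	2.1222116402097035	0.2989491616409493	89.6847484922848
dab	0.29462054902910845	0.14731027451455422	0.44193082354366264
dabth	1.6075859368153513	0.014731027451455422	4.419308235436627
dbc	0.9931979171697517	0.49659895858487585	1.4897968757546276
dbro	0.027250186109972496	0.013625093054986248	0.04087527916495874
dbrt	0.3847118999318387	0.19235594996591934	0.5770678498977581
dc	1.0452575530313732	0.5226287765156866	1.56788632954706
dccl	0.7001745431440272	0.3500872715720136	1.0502618147160407
dcth	0.2982556852359603	0.05226287765156866	15.678863295470599
dg	1.2983471292813433	0.6491735646406717	1.9475206939220149
dgb	0.6613611865978545	0.33068059329892724	0.9920417798967818
dgr	0.6402884378975489	0.32014421894877443	0.9604326568463233
dn	0.02790966520748679	0.02790966520748679	15.678863295470599
drco	0.23575014896748464	0.11787507448374232	0.35362522345122693
drct	0.42253155644903045	0.21126577822451523	0.6337973346735457
drcth	0.07505088127436915	0.011787507448374233	3.5362522345122693
exb	0.6963344790879717	0.3481672395439859	1.0445017186319576
excl	0.6620240023100142	0.3310120011550071	0.9930360034650214
exco	0.5944542667016419	0.29722713335082096	0.8916814000524629
excr	0.26691026609687984	0.13345513304843992	0.40036539914531977
exct	0.5435308018509345	0.27176540092546725	0.8152962027764017
exk	0.1627687023105415	0.08138435115527075	0.24415305346581223
expo	0.6910121175908905	0.34550605879544527	1.0365181763863358
expp	0.11265651798635269	0.056328258993176346	0.16898477697952904
expt	0.6351544434578409	0.31757722172892044	0.9527316651867613
expth	1.4014329428741403	0.034550605879544526	10.365181763863358
exrev	0.6961585444536008	0.3480792722268004	1.0442378166804012
ga	6.783481716386691	3.3917408581933457	10.175222574580037
gar1	1.4029226437123474	0.7014613218561737	2.104383965568521
gar2	5.421596622815254	2.710798311407627	8.13239493422288
gd	0.3348057649043423	0.16740288245217114	0.5022086473565134
gdr1	0.06595562308253258	0.03297781154126629	0.09893343462379887
gdr2	0.4950293650657581	0.24751468253287906	0.7425440475986371
gdrev	0.5654434499157964	0.2827217249578982	0.8481651748736947
grev	12.466960297709331	6.233480148854666	18.700440446563995
hob	0.23525630285874236	0.11762815142937118	0.35288445428811355
hocl	0.23599834725595623	0.11799917362797811	0.3539975208839343
hoo	0.17547080979763435	0.08773540489881718	0.26320621469645156
hor	0.26603987677802976	0.13301993838901488	0.39905981516704464
hot	0.16843168445066156	0.08421584222533078	0.25264752667599233
hoth	2.3171962679963474	0.008773540489881718	2.6320621469645156
inb	0.41135783188943453	0.20567891594471727	0.6170367478341519
inbc	0.4358982070814135	0.21794910354070676	0.6538473106221203
incl	0.3015098656123713	0.15075493280618565	0.45226479841855693
incr	0.2669981732639846	0.1334990866319923	0.40049725989597695
ink	0.6250396101603032	0.3125198050801516	0.9375594152404547
inp	0.5782108660881214	0.2891054330440607	0.8673162991321821
inrev	0.6065966519467002	0.3032983259733501	0.9098949779200503
tlb	1.132332213859646	0.566166106929823	1.698498320789469
tlcl	0.9896060229808528	0.4948030114904264	1.484409034471279
tlco	1.859547819784069	0.9297739098920345	2.7893217296761033
tlct	3.03807867366459	1.519039336832295	4.557118010496885
tlpo	2.2911142456397338	1.1455571228198669	3.4366713684596006
tlpt	0.5548732484606367	0.27743662423031834	0.832309872690955
tlpth	1.7392316868414905	0.11455571228198669	34.36671368459601
tlrev	1.2019643384955014	0.6009821692477507	1.8029465077432523
trb	1.0331851280056683	0.5165925640028342	1.5497776920085025
trcl	0.34986201699671055	0.17493100849835527	0.5247930254950658
trco	2.084325951082247	1.0421629755411235	3.12648892662337
trct	2.426148067355164	1.213074033677582	3.639222101032746
trpo	1.6543909788897313	0.8271954894448657	2.481586468334597
trpt	1.0760631679286763	0.5380315839643381	1.6140947518930144
trpth	1.5123857238608513	0.08271954894448656	24.81586468334597
trrev	1.1323982151593748	0.5661991075796874	1.698597322739062
ub	1.173604862438075	0.5868024312190375	1.7604072936571127
ucl	0.5751528522060346	0.2875764261030173	0.8627292783090519
umb	0.42001831063047057	0.21000915531523529	0.6300274659457059
umcl	0.3936994729998421	0.19684973649992105	0.5905492094997631
umco	0.2257876986507489	0.11289384932537445	0.3386815479761234
umct	0.1524914704122857	0.07624573520614285	0.22873720561842853
umpo	0.3297664963630288	0.1648832481815144	0.4946497445445432
umpt	0.3724548023339948	0.1862274011669974	0.5586822035009922
umpth	0.11108322972697032	0.01648832481815144	4.946497445445432
umrev	0.46418732930041845	0.23209366465020922	0.6962809939506277
upb	2.025557294409379	1.0127786472046896	3.0383359416140685
upcl	1.4246749620525379	0.7123374810262689	2.137012443078807
uppo	1.6514138364302422	0.8257069182151211	2.4771207546453633
uppt	1.9376405516006798	0.9688202758003399	2.9064608274010197
uppth	10.439665045155856	0.08257069182151211	24.77120754645363
uprev	2.5975707523864164	1.2987853761932082	3.8963561285796247
upth	0.9038951704129302	0.03899068902578659	11.697206707735976
upuo	0.7798137805157318	0.3899068902578659	1.1697206707735976
uput	0.20060501005529058	0.10030250502764529	0.3009075150829359
urev	1.3568008126990554	0.6784004063495277	2.035201219048583
uro	0.06828131481286248	0.03414065740643124	0.10242197221929372
urt	0.1636039067906013	0.08180195339530065	0.24540586018590194
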