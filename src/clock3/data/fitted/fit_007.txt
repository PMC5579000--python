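# fitted clock rate set (reduced-scale SRES run, verified
# against the 16-condition registry at dt=0.005, 600 h)
# name	value	range_low	range_high
ab	5.555589389462473	2.7777946947312366	8.33338408419371
abc	6.212815398593436	3.106407699296718	9.319223097890154
abro	12.17050573939931	6.085252869699655	18.255758609098965
abrt	4.745005951627781	2.3725029758138905	7.117508927441671
abth	0.5165932851188083	0.27777946947312365	83.3338408419371
ac	5.842569121017527	2.9212845605087634	8.76385368152629
accl	0.6857073992328576	0.3428536996164288	1.0285610988492864
acth	4.343087662774275	0.29212845605087634	87.63853681526291
ag	1.1734094608404895	0.5867047304202447	1.760114191260734
agb	0.6504701560891512	0.3252350780445756	0.9757052341337267
agr	0.6589272092315163	0.32946360461575813	0.9883908138472743
an	21.719187341691057	0.29212845605087634	87.63853681526291
arco	5.5946199405699	2.79730997028495	8.39192991085485
arct	6.5324787238641395	3.2662393619320698	9.79871808579621
arcth	2.37641376060459	0.279730997028495	83.9192991085485
dab	0.29357023381319164	0.14678511690659582	0.4403553507197875
dabth	1.6745192946498504	0.014678511690659582	4.403553507197875
dbc	1.029991705127041	0.5149958525635205	1.5449875576905616
dbro	0.027611691318676423	0.013805845659338211	0.04141753697801463
dbrt	0.38256887136203377	0.19128443568101688	0.5738533070430507
dc	1.0409237053615195	0.5204618526807597	1.561385558042279
dccl	0.6999310988968991	0.34996554944844954	1.0498966483453487
dcth	0.31463636933569317	0.05204618526807597	15.61385558042279
dg	1.274859154463008	0.637429577231504	1.9122887316945119
dgb	0.6774917236410098	0.3387458618205049	1.0162375854615147
dgr	0.6268717270749155	0.3134358635374577	0.9403075906123732
dn	0.027161110565574277	0.027161110565574277	15.61385558042279
drco	0.22992986414534294	0.11496493207267147	0.34489479621801444
drct	0.4135766882344388	0.2067883441172194	0.6203650323516583
drcth	0.0757226782690343	0.011496493207267148	3.4489479621801444
exb	0.6879147150651496	0.3439573575325748	1.0318720725977244
excl	0.6852159460168782	0.3426079730084391	1.0278239190253173
exco	0.5738488969879328	0.2869244484939664	0.8607733454818993
excr	0.2630786053186137	0.13153930265930686	0.39461790797792057
exct	0.5255891144927497	0.26279455724637485	0.7883836717391246
exk	0.16815945693469	0.084079728467345	0.252239185402035
expo	0.6641171184377836	0.3320585592188918	0.9961756776566755
expp	0.10907059932993914	0.05453529966496957	0.1636058989949087
expt	0.6740920171662784	0.3370460085831392	1.0111380257494176
expth	1.469056725899244	0.03320585592188918	9.961756776566755
exrev	0.6771367318620889	0.33856836593104445	1.0157050977931332
ga	6.671437515571696	3.335718757785848	10.007156273357543
gar1	1.4484446332759662	0.7242223166379831	2.1726669499139493
gar2	5.302240587740634	2.651120293870317	7.953360881610951
gd	0.33908360423637757	0.16954180211818878	0.5086254063545663
gdr1	0.06334836820108884	0.03167418410054442	0.09502255230163326
gdr2	0.4801699108584995	0.24008495542924976	0.7202548662877493
gdrev	0.5704849190597922	0.2852424595298961	0.8557273785896882
grev	12.73920290716397	6.369601453581985	19.108804360745953
hob	0.24475503917416236	0.12237751958708118	0.3671325587612435
hocl	0.23856369182042536	0.11928184591021268	0.35784553773063804
hoo	0.18121015982588431	0.09060507991294216	0.2718152397388265
hor	0.26039892768838296	0.13019946384419148	0.3905983915325745
hot	0.16366550019659043	0.08183275009829521	0.24549825029488564
hoth	2.3570784204927593	0.009060507991294216	2.718152397388265
inb	0.39717382470221607	0.19858691235110804	0.5957607370533241
inbc	0.45797322543055113	0.22898661271527557	0.6869598381458267
incl	0.29484462644335874	0.14742231322167937	0.4422669396650381
incr	0.26613689913519634	0.13306844956759817	0.3992053487027945
ink	0.6291572380135606	0.3145786190067803	0.9437358570203409
inp	0.5713848535180442	0.2856924267590221	0.8570772802770663
inrev	0.5776436012143671	0.28882180060718354	0.8664654018215506
tlb	1.132085918224374	0.566042959112187	1.6981288773365613
tlcl	0.9893891695013136	0.4946945847506568	1.4840837542519705
tlco	1.8608280111427167	0.9304140055713583	2.791242016714075
tlct	2.957151699272787	1.4785758496363934	4.43572754890918
tlpo	2.250148418827486	1.125074209413743	3.3752226282412288
tlpt	0.5454896150564661	0.27274480752823305	0.8182344225846991
tlpth	1.7262217892136769	0.1125074209413743	33.75222628241229
tlrev	1.1559366293541822	0.5779683146770911	1.7339049440312733
trb	1.03554938830952	0.51777469415476	1.5533240824642798
trcl	0.33085441606933397	0.16542720803466698	0.49628162410400095
trco	2.0942925861839394	1.0471462930919697	3.141438879275909
trct	2.3246976750262816	1.1623488375131408	3.4870465125394223
trpo	1.6252923232969307	0.8126461616484654	2.4379384849453962
trpt	1.0501731740690867	0.5250865870345434	1.57525976110363
trpth	1.4953542065679044	0.08126461616484654	24.379384849453963
trrev	1.1309911893985412	0.5654955946992706	1.6964867840978117
ub	1.1780797592482593	0.5890398796241296	1.7671196388723889
ucl	0.5872003342297628	0.2936001671148814	0.8808005013446443
umb	0.40761008629073814	0.20380504314536907	0.6114151294361072
umcl	0.41191221402705996	0.20595610701352998	0.61786832104059
umco	0.23131672068218315	0.11565836034109157	0.34697508102327473
umct	0.14955834675080215	0.07477917337540108	0.22433752012620323
umpo	0.3275542330583222	0.1637771165291611	0.4913313495874833
umpt	0.38195267111016484	0.19097633555508242	0.5729290066652473
umpth	0.11040720991882567	0.01637771165291611	4.913313495874833
umrev	0.46219779909840514	0.23109889954920257	0.6932966986476077
upb	2.1142845361305613	1.0571422680652807	3.1714268041958418
upcl	1.3570415010268193	0.6785207505134097	2.035562251540229
uppo	1.6951194585134524	0.8475597292567262	2.5426791877701787
uppt	1.9540726590059005	0.9770363295029503	2.931108988508851
uppth	10.225189424025356	0.08475597292567262	25.42679187770179
uprev	2.593007954497458	1.296503977248729	3.889511931746187
upth	0.9289745479680891	0.03807060634628932	11.421181903886794
upuo	0.7614121269257863	0.38070606346289315	1.1421181903886795
uput	0.20297571161291098	0.10148785580645549	0.3044635674193665
urev	1.3659196000867484	0.6829598000433742	2.0488794001301227
uro	0.07033173635182097	0.035165868175910484	0.10549760452773145
urt	0.16844331236748167	0.08422165618374083	0.2526649685512225
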