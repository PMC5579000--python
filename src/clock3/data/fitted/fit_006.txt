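# fitted clock rate set (reduced-scale SRES run, verified
# against the 16-condition registry at dt=0.005, 600 h)
# name	value	range_low	range_high
ab	5.816413021547091	2.9082065107735455	8.724619532320636
abc	6.2322401725066525	3.1161200862533263	9.348360258759978
abro	12.147807702229601	6.0739038511148005	18.221711553344402
abrt	4.941879385223392	2.470939692611696	7.412819077835088
abth	0.5230517080302158	0.29082065107735455	87.24619532320636
ac	5.949868382680428	2.974934191340214	8.924802574020642
accl	0.7076573816009568	0.3538286908004784	1.0614860724014352
acth	4.4079947789529985	0.2974934191340214	89.24802574020643
ag	1.2241505928250365	0.6120752964125182	1.8362258892375547
agb	0.651874020672077	0.3259370103360385	0.9778110310081155
agr	0.6553093428460769	0.32765467142303845	0.9829640142691154
an	21.67929292756586	0.2974934191340214	89.24802574020643
arco	5.865438486752426	2.932719243376213	8.79815773012864
arct	6.685003871974342	3.342501935987171	10.027505807961512
arcth	2.4664690340225364	0.2932719243376213	87.98157730128639
dab	0.29980123694031274	0.14990061847015637	0.44970185541046914
dabth	1.4371765132913858	0.014990061847015637	4.497018554104692
dbc	1.026892582534775	0.5134462912673875	1.5403388738021624
dbro	0.028291331034167765	0.014145665517083883	0.042436996551251646
dbrt	0.39350853405897845	0.19675426702948923	0.5902628010884676
dc	1.0189418934651446	0.5094709467325723	1.528412840197717
dccl	0.7200489529237313	0.36002447646186564	1.080073429385597
dcth	0.3154947069283355	0.05094709467325723	15.28412840197717
dg	1.2708520304205866	0.6354260152102933	1.9062780456308799
dgb	0.6942968678297966	0.3471484339148983	1.041445301744695
dgr	0.618523994520868	0.309261997260434	0.927785991781302
dn	0.02612845522728041	0.02612845522728041	15.28412840197717
drco	0.2459811833262265	0.12299059166311326	0.36897177498933975
drct	0.4267229453941425	0.21336147269707126	0.6400844180912137
drcth	0.07226226283559799	0.012299059166311325	3.6897177498933975
exb	0.6888643902454118	0.3444321951227059	1.0332965853681177
excl	0.6924235851987731	0.34621179259938656	1.0386353777981596
exco	0.5619589017537701	0.28097945087688503	0.8429383526306551
excr	0.2589267074160995	0.12946335370804976	0.3883900611241493
exct	0.5456020857516343	0.27280104287581713	0.8184031286274513
exk	0.16930240169345007	0.08465120084672503	0.25395360254017507
expo	0.7074080685143633	0.35370403425718167	1.061112102771545
expp	0.11801222425618745	0.05900611212809372	0.17701833638428116
expt	0.6911499952154693	0.34557499760773464	1.0367249928232039
expth	1.429991823348878	0.035370403425718164	10.611121027715452
exrev	0.7298281587712944	0.3649140793856472	1.0947422381569416
ga	6.654100876628153	3.3270504383140764	9.98115131494223
gar1	1.4503402282358628	0.7251701141179314	2.1755103423537943
gar2	5.415028232257681	2.7075141161288405	8.12254234838652
gd	0.3412818737328867	0.17064093686644335	0.5119228105993301
gdr1	0.06509624579008741	0.032548122895043705	0.09764436868513111
gdr2	0.5040356071455107	0.25201780357275533	0.7560534107182659
gdrev	0.5755036271836659	0.28775181359183294	0.8632554407754989
grev	12.976016148277251	6.488008074138626	19.464024222415876
hob	0.2521146490407317	0.12605732452036586	0.37817197356109755
hocl	0.23960262352128217	0.11980131176064109	0.35940393528192327
hoo	0.1737858608358452	0.0868929304179226	0.2606787912537678
hor	0.26057747521138086	0.13028873760569043	0.3908662128170713
hot	0.1699290465147616	0.0849645232573808	0.2548935697721424
hoth	2.3467406037325937	0.008689293041792261	2.606787912537678
inb	0.4137297757354049	0.20686488786770246	0.6205946636031074
inbc	0.461474909309885	0.2307374546549425	0.6922123639648274
incl	0.30667091393164614	0.15333545696582307	0.4600063708974692
incr	0.2620171320560732	0.1310085660280366	0.3930256980841098
ink	0.6386337742091603	0.31931688710458017	0.9579506613137405
inp	0.5613972491201659	0.28069862456008293	0.8420958736802489
inrev	0.5794144427592299	0.28970722137961497	0.8691216641388448
tlb	1.1133527841582378	0.5566763920791189	1.6700291762373567
tlcl	0.9958693375436206	0.4979346687718103	1.493804006315431
tlco	1.8408577948340885	0.9204288974170443	2.761286692251133
tlct	3.1207290132656733	1.5603645066328367	4.68109351989851
tlpo	2.2705793284936986	1.1352896642468493	3.405868992740548
tlpt	0.5480384593743484	0.2740192296871742	0.8220576890615225
tlpth	1.7825964334823752	0.11352896642468494	34.05868992740548
tlrev	1.1464233651701277	0.5732116825850638	1.7196350477551916
trb	1.001909603203267	0.5009548016016335	1.5028644048049005
trcl	0.3451747568007457	0.17258737840037286	0.5177621352011186
trco	2.147910686234654	1.073955343117327	3.2218660293519807
trct	2.395279602583456	1.197639801291728	3.592919403875184
trpo	1.6880207578317514	0.8440103789158757	2.5320311367476274
trpt	1.0783172857107155	0.5391586428553578	1.6174759285660731
trpth	1.5207382354555135	0.08440103789158757	25.320311367476272
trrev	1.1426144286494795	0.5713072143247397	1.7139216429742192
ub	1.2100514165936114	0.6050257082968057	1.8150771248904172
ucl	0.581085878285184	0.290542939142592	0.871628817427776
umb	0.4319708986049931	0.21598544930249655	0.6479563479074897
umcl	0.4117019632132102	0.2058509816066051	0.6175529448198153
umco	0.23442072557757718	0.11721036278878859	0.35163108836636575
umct	0.1520937191872899	0.07604685959364495	0.22814057878093486
umpo	0.3196015053753697	0.15980075268768484	0.47940225806305453
umpt	0.36980085652512884	0.18490042826256442	0.5547012847876933
umpth	0.11354853636044236	0.015980075268768483	4.794022580630545
umrev	0.4670718159112464	0.2335359079556232	0.7006077238668696
upb	2.0737097394566804	1.0368548697283402	3.1105646091850208
upcl	1.4465308428319639	0.7232654214159819	2.169796264247946
uppo	1.639477498216869	0.8197387491084345	2.4592162473253034
uppt	1.9997959536419996	0.9998979768209998	2.9996939304629993
uppth	10.20948389044487	0.08197387491084344	24.592162473253033
uprev	2.64205928500516	1.32102964250258	3.96308892750774
upth	0.9364914125975334	0.038232391820048256	11.469717546014477
upuo	0.7646478364009651	0.38232391820048256	1.1469717546014477
uput	0.19403817920754335	0.09701908960377167	0.291057268811315
urev	1.3786346426409404	0.6893173213204702	2.0679519639614106
uro	0.06874491354996552	0.03437245677498276	0.10311737032494828
urt	0.1620570734152864	0.0810285367076432	0.24308561012292962
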