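# fitted clock rate set (reduced-scale SRES run, verified
# against the 16-condition registry at dt=0.005, 600 h)
# name	value	range_low	range_high
ab	5.743880812336207	2.8719404061681035	8.61582121850431
abc	6.375895604187316	3.187947802093658	9.563843406280974
abro	12.294414049562182	6.147207024781091	18.441621074343274
abrt	4.776979068729099	2.3884895343645494	7.1654686030936485
abth	0.49854617201250845	0.28719404061681036	86.1582121850431
ac	5.842107509185052	2.921053754592526	8.763161263777578
accl	0.7075323333916288	0.3537661666958144	1.0612985000874433
acth	4.431248266367347	0.2921053754592526	87.63161263777577
ag	1.1553081280482866	0.5776540640241433	1.73296219207243
agb	0.672997869149583	0.3364989345747915	1.0094968037243746
agr	0.6560925050554299	0.32804625252771497	0.9841387575831448
an	21.727320971801817	0.2921053754592526	87.63161263777577
arco	5.697568277419473	2.8487841387097363	8.54635241612921
arct	6.490098076264574	3.245049038132287	9.735147114396861
arcth	2.374211226426734	0.2848784138709736	85.4635241612921
dab	0.2900420524504901	0.14502102622524504	0.4350630786757351
dabth	1.576489677334504	0.014502102622524504	4.3506307867573515
dbc	1.0546488029655594	0.5273244014827797	1.5819732044483392
dbro	0.02886997388661437	0.014434986943307184	0.04330496082992155
dbrt	0.3849185027293377	0.19245925136466885	0.5773777540940066
dc	1.076686784574538	0.538343392287269	1.615030176861807
dccl	0.7057363746370661	0.35286818731853303	1.058604561955599
dcth	0.3366161153778952	0.0538343392287269	16.15030176861807
dg	1.267623708290083	0.6338118541450415	1.9014355624351245
dgb	0.693427234564125	0.3467136172820625	1.0401408518461874
dgr	0.6149517863191178	0.3074758931595589	0.9224276794786768
dn	0.0281781153865399	0.0281781153865399	16.15030176861807
drco	0.24130917459640078	0.12065458729820039	0.36196376189460117
drct	0.426120361464003	0.2130601807320015	0.6391805421960045
drcth	0.07324386075204303	0.012065458729820039	3.6196376189460118
exb	0.7030084104305562	0.3515042052152781	1.0545126156458342
excl	0.7043573667251466	0.3521786833625733	1.05653605008772
exco	0.5774294106320408	0.2887147053160204	0.8661441159480612
excr	0.2781743784954756	0.1390871892477378	0.41726156774321344
exct	0.5509077647093468	0.2754538823546734	0.8263616470640202
exk	0.16983352091556872	0.08491676045778436	0.2547502813733531
expo	0.6941888760006453	0.34709443800032264	1.0412833140009679
expp	0.1178246915509113	0.05891234577545565	0.17673703732636695
expt	0.7181881633541357	0.35909408167706786	1.0772822450312036
expth	1.4692754143287727	0.03470944380003226	10.412833140009678
exrev	0.680987725441771	0.3404938627208855	1.0214815881626564
ga	6.67944650994995	3.339723254974975	10.019169764924925
gar1	1.4520310652011912	0.7260155326005956	2.178046597801787
gar2	5.440160235706896	2.720080117853448	8.160240353560344
gd	0.3466581556420295	0.17332907782101475	0.5199872334630442
gdr1	0.06482741047337744	0.03241370523668872	0.09724111571006616
gdr2	0.49211840901106974	0.24605920450553487	0.7381776135166046
gdrev	0.5706908257475586	0.2853454128737793	0.8560362386213378
grev	12.74147683190126	6.37073841595063	19.11221524785189
hob	0.24490486350273794	0.12245243175136897	0.3673572952541069
hocl	0.2381742369932815	0.11908711849664075	0.3572613554899222
hoo	0.18124298867193972	0.09062149433596986	0.27186448300790955
hor	0.25402375335775906	0.12701187667887953	0.3810356300366386
hot	0.16887322756988102	0.08443661378494051	0.25330984135482154
hoth	2.331652217683819	0.009062149433596987	2.7186448300790955
inb	0.4122564341912345	0.20612821709561724	0.6183846512868517
inbc	0.45462797766650453	0.22731398883325227	0.6819419664997568
incl	0.3046042649352204	0.1523021324676102	0.4569063974028306
incr	0.26425676920801433	0.13212838460400717	0.3963851538120215
ink	0.6313810304537768	0.3156905152268884	0.9470715456806652
inp	0.5749084359322567	0.28745421796612836	0.8623626538983851
inrev	0.6022047380710497	0.30110236903552484	0.9033071071065746
tlb	1.1392842248153778	0.5696421124076889	1.7089263372230667
tlcl	1.0149986690868966	0.5074993345434483	1.522498003630345
tlco	1.856564820000467	0.9282824100002335	2.7848472300007003
tlct	2.995749274842973	1.4978746374214864	4.493623912264459
tlpo	2.304378435650321	1.1521892178251605	3.4565676534754814
tlpt	0.5575927920630777	0.27879639603153883	0.8363891880946165
tlpth	1.6802407616937745	0.11521892178251605	34.565676534754814
tlrev	1.1475121269114648	0.5737560634557324	1.7212681903671971
trb	1.0631907147859263	0.5315953573929632	1.5947860721788896
trcl	0.33094876924639804	0.16547438462319902	0.49642315386959707
trco	2.1157900332588437	1.0578950166294219	3.173685049888266
trct	2.379159841696522	1.189579920848261	3.5687397625447828
trpo	1.8179786051437654	0.9089893025718827	2.726967907715648
trpt	1.069663751310427	0.5348318756552135	1.6044956269656405
trpth	1.4763703018846097	0.09089893025718827	27.269679077156482
trrev	1.1493213684990211	0.5746606842495106	1.7239820527485317
ub	1.2084333284965554	0.6042166642482777	1.812649992744833
ucl	0.5949940117901802	0.2974970058950901	0.8924910176852703
umb	0.40550032985461815	0.20275016492730907	0.6082504947819272
umcl	0.4034819874066489	0.20174099370332446	0.6052229811099734
umco	0.23029885350565665	0.11514942675282833	0.34544828025848495
umct	0.14917704823297676	0.07458852411648838	0.22376557234946515
umpo	0.3205512460229512	0.1602756230114756	0.48082686903442684
umpt	0.3919168650851259	0.19595843254256295	0.5878752976276889
umpth	0.10960219960412843	0.01602756230114756	4.808268690344269
umrev	0.46035885704322965	0.23017942852161483	0.6905382855648445
upb	2.0364365069994435	1.0182182534997217	3.054654760499165
upcl	1.3790332573848125	0.6895166286924063	2.0685498860772187
uppo	1.6344937897387726	0.8172468948693863	2.4517406846081586
uppt	1.982570052501224	0.991285026250612	2.973855078751836
uppth	10.429055099054814	0.08172468948693863	24.517406846081585
uprev	2.6010139069258225	1.3005069534629112	3.9015208603887337
upth	0.9024736327273646	0.040176214626873666	12.0528643880621
upuo	0.8035242925374733	0.40176214626873663	1.20528643880621
uput	0.2022305491592535	0.10111527457962675	0.30334582373888025
urev	1.3921034982130958	0.6960517491065479	2.0881552473196434
uro	0.07078765860171939	0.03539382930085969	0.10618148790257909
urt	0.16437793391069866	0.08218896695534933	0.246566900866048
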