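gene	s001	s002	s003	s004	s005	s006	s007	s008	s009
g0001	0.45131777084572233	0.6203791453926248	0.706832084885324	3.8786311048355837	3.7973020462420357	3.362416461050193	7.1130301861337895	7.154684695801471	7.351207011956166
g0002	-7.188082776904846	-6.831005317540017	-5.116514732922163	-3.5553348757580565	-3.8120510877179257	-5.624143480798971	-7.917611770337934	-4.793455732821266	-3.110014370751732
g0003	3.034769047983628	2.567999860086714	2.886206259388245	-1.1572301327854488	-1.5007919321696346	-1.1073717454521326	-5.44290094009396	-6.021903874429302	-6.08065706735
g0004	0.17921901139213503	2.2665947937233306	0.2697704796816265	2.3974085152022333	0.4756325351573416	1.0062444840845128	0.36922114323001387	2.3497963066627636	2.0842766288288774
g0005	-1.996713679021983	-3.828858487955222	-2.633200530066303	-4.109223427468979	-3.0185202115780556	-2.098332630828473	-2.221681547478746	-0.05083390802334753	-2.1451412297670296
g0006	1.3483314474940178	1.0741614454103148	1.7437053070395683	1.2297783236328959	2.1525016500849232	0.34643593293030106	1.1091190658971222	0.8063387607552169	0.8010812349072199
g0007	-2.364662488958743	-3.1130282477504334	-2.768633350315514	-1.0843011317682172	0.0659796075252137	-4.6172999595308895	-2.1909568396680608	-2.8618448927370643	-3.3837727194605316
g0008	4.87581474230018	3.02675422606282	3.316702050667419	3.134075083089035	5.091072373909077	4.665062447299019	3.700263817386509	5.052514484829333	3.4470226833301503
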