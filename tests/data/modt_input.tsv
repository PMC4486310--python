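feature	tr_d00_r1	tr_d00_r2	pa_d00_r1	pa_d00_r2	tr_d07_r1	tr_d07_r2	pa_d07_r1	pa_d07_r2	tr_d14_r1	tr_d14_r2	pa_d14_r1	pa_d14_r2
F001	8.939391713	8.823700982	8.989804163	8.923028288	9.418336232	8.997648635	9.137268715	8.986507888	9.432063136	8.964081555	9.000013256	8.787259403
F002	8.110363932	8.09047859	8.315069021	8.31158988	8.48727015	8.151646317	8.157610448	8.012124211	8.120371436	7.916648732	8.023206371	8.057490537
F003	9.309915243	9.36037662	8.992197119	9.036451803	9.50207332	9.477279432	8.510949211	8.282769138	9.046784662	8.94988189	9.283206712	9.271389236
F004	8.574211621	8.843415576	7.650591601	7.251529113	8.365810445	8.163211873	8.290716047	8.266148838	7.744002676	7.488201136	8.362563479	8.241248381
F005	8.962612839	9.470585092	9.518603718	9.778902755	10.04776803	9.621369826	10.0772956	10.02584439	8.184684315	9.269970599	8.692947921	8.76170511
F006	8.4761906	8.495873966	6.994635949	6.553399699	6.456745824	7.016253114	6.217384046	6.96399185	6.718879502	6.638296287	7.18051074	5.631453531
F007	8.002099174	8.193793264	8.654958588	8.603516657	8.352989211	8.586526683	8.02269151	8.229811134	8.605378737	8.854875725	8.25067295	8.40543142
F008	9.924897747	9.979586407	9.330757367	9.394967905	9.673602576	9.809791467	9.584323149	9.699935243	9.112891003	9.275391214	9.968463177	9.97016089
F009	10.34185182	10.12916776	10.44200874	10.80635913	10.09213197	9.502073974	10.07771534	10.32894389	9.869389915	9.828655718	10.34134609	10.46141777
F010	6.536733291	6.570779438	6.620682792	6.78676482	7.372389983	7.326460469	6.937263428	6.95366504	7.031731823	6.811784432	6.733812744	7.263484326
F011	10.45895554	10.87946198	10.30823273	10.17997887	10.54323725	10.29405305	9.604004714	10.08547792	9.376327413	9.297431229	10.30199912	9.992359567
F012	11.19429313	11.45975326	10.80596184	10.75474351	9.695081628	9.816226163	10.17479923	9.958938618	10.33939294	10.33070209	9.47360807	9.610638051
F013	11.1492407	11.2860848	11.07676492	11.2363857	11.09990963	10.93764255	10.88205838	10.77327663	11.47232957	10.8107207	10.85628172	10.84881287
F014	6.979339895	7.083277693	8.095079043	8.410976348	7.258268233	7.283931096	7.907716375	7.77528368	7.736704993	7.910189457	7.876946872	8.001208889
F015	8.292904374	8.285515884	8.437602306	8.257261341	8.448592396	8.299635379	8.504306579	7.698415859	9.488185447	9.435401875	8.078420487	7.82216063
F016	7.216803511	7.256279951	7.187773906	7.230445907	7.154473601	7.156622936	7.426767537	6.928038263	7.32827179	7.33320729	7.598751419	7.12092511
F017	11.52050644	11.92885814	11.74640562	11.50202721	11.80936861	11.60710015	11.81253085	11.51169132	11.78526706	12.01836734	11.56072102	11.61271539
F018	7.638349315	8.204300228	7.717556463	7.815924538	7.696779448	7.976453375	8.072316151	8.149933343	7.874264836	8.364802989	7.602791731	7.961567406
F019	10.81718121	10.98315941	10.85385329	10.80957901	11.378613	11.00515817	11.17383284	11.24001742	11.02424755	10.80251486	11.07395414	10.7990075
F020	11.43158812	12.14097641	11.78604785	11.08805866	10.79792492	10.74787254	11.4373956	11.06132878	11.28723881	11.14939094	11.26431032	10.95634336
F021	7.260457437	5.910640264	7.071443259	6.454640847	6.788531662	6.543393612	5.906222263	6.67783893	6.349600339	6.133819777	6.375781753	6.402297933
F022	9.482899384	9.329860584	8.921040656	9.39208045	9.593801063	10.03302626	9.162387818	9.191485387	9.771818632	9.593972068	9.324785248	9.46963034
F023	8.432081527	9.774700297	9.038608674	8.379586142	9.037297773	9.890219945	10.42072067	9.925940039	9.982385392	9.784566037	8.046604624	7.857832343
F024	6.768246653	7.054514423	6.772475962	6.654623555	7.452070263	7.700968742	7.077906021	7.352428528	8.063482866	7.583991721	7.478717053	7.175448218
F025	9.268987819	9.351343859	9.194719088	9.167378565	9.437770757	9.739114622	9.404051227	9.572479295	9.187369078	9.420351058	9.605039031	9.562122084
F026	9.051289196	8.701654138	8.428864254	8.972286707	8.605443745	9.246275606	8.653775368	9.139322462	8.365591673	8.727786866	8.971832553	9.331874965
F027	10.29595638	10.06274338	10.43206406	10.39544773	10.17461181	10.25274127	10.38299133	9.965779024	10.29156501	10.35496976	10.35060862	10.47016808
F028	10.25147895	10.63180977	10.09746282	10.13744325	10.14234081	9.888193668	10.11906881	9.933907397	10.17813419	9.960835389	9.96847249	10.24790933
F029	9.839594926	9.610403594	9.660169765	9.620776959	9.821021031	9.630911064	10.02256361	9.689164006	9.892435249	10.04553914	9.828291161	9.706077859
F030	7.483205737	7.557102634	7.485685883	7.487133927	7.658969089	7.758159634	7.838605313	7.571901922	7.571820577	7.651769475	7.741146027	7.545429399
F031	6.929979869	6.753320733	5.593761725	4.782526618	7.40840243	6.130517875	6.308648241	7.481965807	7.160126649	6.460306902	6.42514317	7.097900064
F032	10.23582118	10.3635447	10.03983897	9.75206019	10.0463953	10.13189459	10.36854782	10.39521119	9.858798482	10.1816932	10.18355291	10.26719354
F033	8.631788539	8.445264369	8.304993419	7.610459259	8.957750103	8.942702491	7.858020138	8.072526167	8.524329515	8.485203406	8.879359354	8.913583401
F034	9.044651934	9.198451148	7.801408377	8.044904201	9.578339079	9.733451053	9.90681921	9.469254769	9.853996704	9.82739492	10.27964442	10.47599722
F035	7.579324646	7.6044787	7.006188969	7.126772598	7.690944141	7.941863225	9.382652548	9.252559372	8.432767218	8.431868969	7.705574298	7.789041439
F036	8.267995098	8.580724808	8.42364657	8.594102726	8.754050855	8.629475461	8.488989081	8.556234685	8.452381955	8.265921702	8.579790527	8.643532811
F037	9.091778978	9.358296066	8.360820153	8.048696801	8.429590886	8.105769017	9.05649547	9.38124408	9.201209017	8.417950684	9.601056309	8.245258469
F038	6.810249062	6.729969073	8.186471797	7.651199786	7.514989942	7.190212263	6.886225354	7.243953238	7.351861336	8.52424381	7.644549558	7.621095577
F039	7.557097561	7.327470013	8.211904483	8.029139847	7.925494323	8.073048575	6.499533376	6.769572856	7.2799074	7.318048602	7.398413431	7.620810014
F040	6.065086366	5.844046494	5.831140899	6.099826822	6.161924918	6.335532778	6.806740562	7.027817488	6.380802342	6.177187342	7.611836001	7.156744081
F041	9.177219993	9.554548341	8.559140523	8.031890129	8.977080357	8.87417196	8.778159647	8.432732454	8.453581931	7.799633107	8.319358831	8.345641707
F042	7.748267131	7.517224843	7.819807889	7.454009897	7.530270704	7.709994668	7.818852812	7.804330724	7.593557169	7.913541315	7.729002697	8.029336949
F043	11.22911565	11.19540226	10.73938552	11.18825909	10.15798955	10.10795305	11.43216523	11.52613591	11.42415505	10.67913282	9.821200297	10.3011661
F044	10.20178987	10.05110469	9.132764819	9.773929235	9.48446469	9.396387308	9.684661967	9.325831033	10.20738102	9.56656974	9.399223691	9.556443333
F045	12.36498589	12.59918924	11.32656788	11.24535412	11.47225463	11.28354168	11.21889542	11.22495921	9.981042651	10.26984137	11.40078113	11.22215265
F046	11.68240129	11.57521904	11.88077879	11.68705898	11.64042178	12.02780168	11.10768815	12.10232494	11.90487544	12.10615043	12.28731492	11.64118592
F047	11.01576996	10.83407865	10.28086814	10.04484422	10.2007014	10.00685507	9.077454045	9.177204538	9.476814938	9.628523039	8.538319807	8.922624868
F048	11.75525358	11.69103982	11.94260773	11.87653951	11.72754502	11.68106665	11.37714882	11.7801108	11.02557035	11.08675618	10.99750988	10.96214354
F049	7.58616399	7.687896649	7.856719213	7.828377264	7.956853864	7.793496325	7.282573268	7.203840288	7.544819078	7.060668438	8.44864026	8.308793229
F050	11.68796534	11.92488503	10.65243189	11.04286643	11.67282841	11.81854198	12.0130757	11.99946774	12.18576589	12.44794286	11.2721411	11.52026146
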