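proteolysis	synthetic demo set (membership is random, not curated biology)	g00028	g00069	g00127	g00155	g00181	g00240	g00244	g00332	g00376	g00382	g00473	g00537	g00669	g00790	g00858	g00873	g00961	g01066	g01100	g01126	g01335	g01382	g01425	g01496	g01509	g01645	g01816	g01917	g01921	g01992
lipid_metabolism	synthetic demo set (membership is random, not curated biology)	g00129	g00205	g00289	g00326	g00367	g00568	g00607	g00776	g00815	g00990	g01006	g01170	g01324	g01438	g01564	g01599	g01631	g01756	g01804	g01823	g01864	g01879	g01889	g01954	g01976
chromatin_remodeling	synthetic demo set (membership is random, not curated biology)	g00112	g00122	g00137	g00178	g00422	g00464	g00555	g00556	g00564	g00600	g00605	g00658	g00675	g00711	g00757	g00931	g00951	g00958	g01021	g01058	g01227	g01435	g01461	g01471	g01482	g01523	g01630	g01669	g01791	g01836	g01878	g01901	g01906	g01923	g01930
neuronal_function	synthetic demo set (membership is random, not curated biology)	g00050	g00103	g00115	g00320	g00416	g00489	g00507	g00589	g00597	g00630	g00637	g00651	g00710	g00798	g00870	g00948	g00976	g01201	g01216	g01218	g01221	g01238	g01244	g01255	g01258	g01279	g01297	g01304	g01396	g01437	g01442	g01535	g01540	g01541	g01640	g01701	g01713	g01772	g01974	g01995
stress_response	synthetic demo set (membership is random, not curated biology)	g00063	g00064	g00078	g00125	g00401	g00491	g00508	g00683	g00936	g00995	g01111	g01169	g01263	g01427	g01621	g01674	g01771	g01845	g01875	g01947
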