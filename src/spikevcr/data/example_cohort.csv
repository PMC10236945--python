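id,sample,spikes_used,transition_type,size,bands,threshold,outcome,in_out,model_performance
1,step1,131,D->D,18,"6,7,8,9,10,11,12",0.18,favourable,in,Success
2,step1,108,D->D,19,"7,8,9,10",0.10,favourable,in,Success
3,step1,32,S->S,15,"7,8,9,10",0.89,unfavourable,out,Success
4,step1,66,D->D,16,"6,7,8,9",0.26,favourable,in,Success
5,step1,89,D->D,16,"7,8,9,10,11",0.14,favourable,in,Success
6,step1,66,S->S,22,"3,4,5,6,7",0.28,unfavourable,out,Success
7,step1,22,S->S,18,"7,8,9,10,11",0.75,favourable,in,Success
8,step1,24,D->D,22,"6,7,8,9,10",0.67,favourable,in,Success
9,step1,30,D->D,16,"8,9,10,11",0.48,favourable,out,Failure
10,step1,64,D->D,24,"7,8,9,10,11",0.32,unfavourable,in,Failure
11,step1,50,D->D,16,"9,10,11,12",0.31,favourable,in,Success
12,step1,25,D->D,20,"8,9,10,11",0.56,favourable,in,Success
13,step1,28,S->S,5,"3,4,5,6,7",0.86,unfavourable,out,Success
14,step1,23,D->D,10,"5,6,7,8",0.72,favourable,out,Failure
15,step2,37,D->D,19,"1,2,3,4",0.57,favourable,in,Success
16,step2,28,D->D,16,"8,9,10,11",0.37,unfavourable,out,Success
17,step2,23,D->D,15,"6,7,8,9",0.54,unfavourable,out,Success
18,step2,20,D->D,32,"6,7,8,9,10",0.82,unfavourable,out,Success
19,step2,24,D->D,16,"8,9,10,11",0.70,unfavourable,out,Success
20,step2,20,D->D,15,"8,9,10,11,12",0.55,unfavourable,in,Failure
21,step2,28,D->D,27,"7,8,9,10,11",0.39,favourable,out,Failure
22,step2,20,D->D,16,"8,9,10,11",0.36,favourable,in,Success
23,step2,21,S->S,19,"6,7,8,9,10",0.90,unfavourable,out,Success
24,step2,46,S->S,5,"1,2,3,4",0.92,unfavourable,out,Success
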