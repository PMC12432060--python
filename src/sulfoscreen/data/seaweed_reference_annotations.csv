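id,name,base_aglycone,n_sulfates,rt_min,formula,molecular_weight,experimental_mz,delta_ppm,diagnostic_ions,confidence_level
1,Phloroglucinol sulfate,phloroglucinol,1,0.6,C6H6O6S,205.9883,204.9811,-0.8,204.9813;125.0243;79.9569,2
2,Diphloroethol disulfate,diphloroethol,2,0.7,C12H10O12S2,409.9613,408.9540,-0.2,328.9972;249.0403;141.0193;140.0114;125.0243;79.9565,2
3,Diphloroethol trisulfate,diphloroethol,3,0.7,C12H10O15S3,489.9188,488.9115,1.2,408.9536;328.9972;249.0403;141.0193;140.0114;125.0243;79.9565,3
4,Catechol sulfate,catechol,1,0.8,C6H6O5S,189.9932,188.9859,-2.4,188.9855;109.0289;79.9565,3
5,Diphloroethol sulfate,diphloroethol,1,0.8,C12H10O9S,330.0045,328.9972,-0.2,328.9972;249.0403;141.0193;140.0114;125.0243,2
6,Diphloroethol,diphloroethol,0,0.8,C12H10O6,250.0477,249.0404,-0.1,249.0400;141.0193;125.0243,2
7,Hydroxymethoxybenzoic acid sulfate,hydroxymethoxybenzoic acid,1,0.9,C8H8O7S,247.9983,246.9911,-3.0,246.9907;203.0012;123.0290;108.0211;80.9644;79.9566,3
8,Dihydroxyphenyllactic sulfate 1,dihydroxyphenyllactic acid,1,1.0,C9H10O8S,278.0087,277.0014,-3.5,277.0014;197.0449;179.0340;135.0445;96.9596;72.9922,2
9,Dihydroxyphenyllactic disulfate,dihydroxyphenyllactic acid,2,1.0,C9H10O11S2,357.9652,356.9580,-3.4,277.0014;197.0449;179.0340;135.0445;96.9596;79.9565;72.9922,2
10,Dihydroxybenzoic acid,dihydroxybenzoic acid,0,1.3,C7H6O4,154.0264,153.0191,-1.6,153.0188;109.0291,2
11,Dihydroxyphenyllactic sulfate 2,dihydroxyphenyllactic acid,1,1.3,C9H10O8S,278.0092,277.0019,-1.7,277.0014;197.0449;179.0340;135.0445;123.0447;79.9565;72.9922,3
12,Dihydroxybenzoic acid sulfate,dihydroxybenzoic acid,1,1.3,C7H6O7S,233.9830,232.9757,-1.9,232.9753;153.0188;109.0291,2
13,Hydroxybenzaldehyde isomer sulfate,hydroxybenzaldehyde,1,1.4,C7H6O5S,201.9928,200.9855,-4.0,200.9864;121.0289;79.9565,3
14,Triphloroethol,triphloroethol,0,1.4,C18H14O9,374.0638,373.0566,0.1,373.0574;247.0244;229.0138;201.0190;125.0242,2
15,Hydroxybenzoic acid sulfate,hydroxybenzoic acid,1,1.4,C7H6O6S,217.9876,216.9803,-4.2,216.9802;137.0238;93.0339,2
16,Phenol sulfate,phenol,1,1.5,C6H6O4S,173.9980,172.9907,-3.9,172.9906;93.0340;79.9566,2
17,Hydroxyphenyllactic acid sulfate,hydroxyphenyllactic acid,1,1.5,C9H10O7S,262.0137,261.0064,-4.0,261.0064;181.0505;163.0399;135.0451;119.0501;79.9565,2
18,Triphloroethol sulfate,triphloroethol,1,1.5,C18H14O12S,454.0210,453.0137,0.8,453.0130;373.0574;247.0244;229.0138;201.0190;125.0242;79.9565,2
19,Hydroxyphenyllactic acid,hydroxyphenyllactic acid,0,1.6,C9H10O4,182.0579,181.0506,-0.3,181.0505;163.0399;135.0451;119.0501;101.0241;89.0240,2
20,Hydroxytyrosol sulfate,hydroxytyrosol,1,1.7,C8H10O6S,234.0193,233.0120,-2.3,233.0118;153.0553;123.0449;79.9567,2
21,Dihydroxyphenylacetic acid,dihydroxyphenylacetic acid,0,1.8,C8H8O4,168.0419,167.0346,-2.5,167.0342;123.0446,3
22,Dihydroxyphenylacetic acid sulfate,dihydroxyphenylacetic acid,1,1.8,C8H8O7S,247.9988,246.9915,-1.1,246.9909;167.0342;123.0446;79.9567,2
23,Dihydroxycoumarin 1,dihydroxycoumarin,0,1.9,C9H6O4,178.0261,177.0188,-3.2,177.0184;133.0292,3
24,Hydroxyphenylacetic acid sulfate,hydroxyphenylacetic acid,1,2.0,C8H8O6S,232.0031,230.9958,-4.6,230.9960;151.0396;107.0499;79.9567,2
25,Tyrosol sulfate,tyrosol,1,2.0,C8H10O5S,218.0252,217.0179,1.4,217.0164;137.0607;79.9568,2
26,Hydroxyphenylacetic acid,hydroxyphenylacetic acid,0,2.0,C8H8O3,152.0473,151.0400,-0.5,151.0396;107.0499,2
27,Hydroxymethoxyphenylacetic acid sulfate,hydroxymethoxyphenylacetic acid,1,2.3,C9H10O7S,262.0141,261.0068,-2.6,261.0064;181.0505;122.0267,3
28,Hydroxybenzaldehyde sulfate,hydroxybenzaldehyde,1,2.4,C7H6O5S,201.9932,200.9859,-2.0,200.9864;121.0289;93.0343;79.9565,2
29,Dihydroxybenzaldehyde sulfate,dihydroxybenzaldehyde,1,2.7,C7H6O6S,217.9875,216.9802,-4.6,216.9801;137.0237;109.0291;108.0211;80.9643;79.9565,2
30,Caffeic acid,caffeic acid,0,3.5,C9H8O4,180.0419,179.0347,-1.8,179.0345;135.0448,2
31,Dihydroxymethylcoumarin,dihydroxymethylcoumarin,0,3.9,C10H8O4,192.0418,191.0346,-2.3,191.0341;147.0444;93.0338,3
32,Phloretic acid sulfate,phloretic acid,1,4.2,C9H10O6S,246.0197,245.0124,-0.5,245.0124;165.0548;121.0658;93.0342;79.9569,3
33,Caffeic acid isomer 1,caffeic acid,0,4.2,C9H8O4,180.0417,179.0345,-2.9,179.0343;135.0448;109.0291,3
34,Phenyllactic acid sulfate,phenyllactic acid,1,4.9,C9H10O6S,246.0187,245.0114,-4.7,165.0555;147.0451;119.0501;96.9595;72.9926,2
35,Phenyllactic acid,phenyllactic acid,0,5.3,C9H10O3,166.0627,165.0555,-1.5,165.0555;147.0451;119.0501;72.9926,2
36,Dihydroxycoumarin 2,dihydroxycoumarin,0,5.3,C9H6O4,178.0261,177.0188,-3.1,177.0184;133.0292,3
37,Coumaric acid,coumaric acid,0,5.8,C9H8O3,164.0468,163.0395,-3.6,163.0391;119.0496,2
38,Caffeic acid isomer 2,caffeic acid,0,6.2,C9H8O4,180.0418,179.0345,-2.6,179.0343;135.0448;109.0291,3
39,Phloretic acid isomer 1,phloretic acid,0,6.3,C9H10O3,166.0627,165.0554,-1.7,165.0548;121.0658;93.0342,3
40,Phloretic acid isomer 2,phloretic acid,0,6.7,C9H10O3,166.0626,165.0553,-2.3,165.0548;121.0658;93.0342,3
41,Dihydroxydimethylcoumarin 1,dihydroxydimethylcoumarin,0,7.2,C11H10O4,206.0576,205.0503,-1.6,205.0501;161.0602;93.0340;75.0080,3
42,Phloretic acid isomer 3,phloretic acid,0,7.3,C9H10O3,166.0624,165.0551,-3.8,165.0548;121.0658;95.0495;93.0342,3
43,Dihydroxydimethylcoumarin 2,dihydroxydimethylcoumarin,0,7.7,C11H10O4,206.0577,205.0504,-1.2,205.0501;161.0602;133.0656,3
44,Dihydroxydimethylcoumarin sulfate,dihydroxydimethylcoumarin,1,8.6,C11H10O7S,286.0149,285.0077,0.7,295.0075;205.0501;161.0602;133.0656,3
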