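node_id,name,hemisphere,is_reward_node
10,lh-thalamus,left,0
11,lh-caudate,left,1
12,lh-putamen,left,1
13,lh-pallidum,left,0
17,lh-hippocampus,left,0
18,lh-amygdala,left,0
26,lh-accumbens,left,1
49,rh-thalamus,right,0
50,rh-caudate,right,1
51,rh-putamen,right,1
52,rh-pallidum,right,0
53,rh-hippocampus,right,0
54,rh-amygdala,right,0
58,rh-accumbens,right,1
1001,ctx-lh-bankssts,left,0
1002,ctx-lh-caudalanteriorcingulate,left,0
1003,ctx-lh-caudalmiddlefrontal,left,0
1005,ctx-lh-cuneus,left,0
1006,ctx-lh-entorhinal,left,0
1007,ctx-lh-fusiform,left,0
1008,ctx-lh-inferiorparietal,left,0
1009,ctx-lh-inferiortemporal,left,0
1010,ctx-lh-isthmuscingulate,left,0
1011,ctx-lh-lateraloccipital,left,0
1012,ctx-lh-lateralorbitofrontal,left,1
1013,ctx-lh-lingual,left,0
1014,ctx-lh-medialorbitofrontal,left,1
1015,ctx-lh-middletemporal,left,0
1016,ctx-lh-parahippocampal,left,0
1017,ctx-lh-paracentral,left,0
1018,ctx-lh-parsopercularis,left,0
1019,ctx-lh-parsorbitalis,left,0
1020,ctx-lh-parstriangularis,left,0
1021,ctx-lh-pericalcarine,left,0
1022,ctx-lh-postcentral,left,0
1023,ctx-lh-posteriorcingulate,left,0
1024,ctx-lh-precentral,left,0
1025,ctx-lh-precuneus,left,0
1026,ctx-lh-rostralanteriorcingulate,left,0
1027,ctx-lh-rostralmiddlefrontal,left,0
1028,ctx-lh-superiorfrontal,left,0
1029,ctx-lh-superiorparietal,left,0
1030,ctx-lh-superiortemporal,left,0
1031,ctx-lh-supramarginal,left,0
1032,ctx-lh-frontalpole,left,0
1033,ctx-lh-temporalpole,left,0
1034,ctx-lh-transversetemporal,left,0
1035,ctx-lh-insula,left,0
2001,ctx-rh-bankssts,right,0
2002,ctx-rh-caudalanteriorcingulate,right,0
2003,ctx-rh-caudalmiddlefrontal,right,0
2005,ctx-rh-cuneus,right,0
2006,ctx-rh-entorhinal,right,0
2007,ctx-rh-fusiform,right,0
2008,ctx-rh-inferiorparietal,right,0
2009,ctx-rh-inferiortemporal,right,0
2010,ctx-rh-isthmuscingulate,right,0
2011,ctx-rh-lateraloccipital,right,0
2012,ctx-rh-lateralorbitofrontal,right,1
2013,ctx-rh-lingual,right,0
2014,ctx-rh-medialorbitofrontal,right,1
2015,ctx-rh-middletemporal,right,0
2016,ctx-rh-parahippocampal,right,0
2017,ctx-rh-paracentral,right,0
2018,ctx-rh-parsopercularis,right,0
2019,ctx-rh-parsorbitalis,right,0
2020,ctx-rh-parstriangularis,right,0
2021,ctx-rh-pericalcarine,right,0
2022,ctx-rh-postcentral,right,0
2023,ctx-rh-posteriorcingulate,right,0
2024,ctx-rh-precentral,right,0
2025,ctx-rh-precuneus,right,0
2026,ctx-rh-rostralanteriorcingulate,right,0
2027,ctx-rh-rostralmiddlefrontal,right,0
2028,ctx-rh-superiorfrontal,right,0
2029,ctx-rh-superiorparietal,right,0
2030,ctx-rh-superiortemporal,right,0
2031,ctx-rh-supramarginal,right,0
2032,ctx-rh-frontalpole,right,0
2033,ctx-rh-temporalpole,right,0
2034,ctx-rh-transversetemporal,right,0
2035,ctx-rh-insula,right,0
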