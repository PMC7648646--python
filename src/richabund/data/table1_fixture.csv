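# Published per-region model-selection results for 23 forest regions, transcribed
# from the regional BIC comparison table of the source study (values as printed).
# Columns: n = number of plots; bic_msh / bic_mih / bic_null = BIC of the
# richness->abundance, abundance->richness and no-link candidate SEMs;
# delta_bic_printed = printed BIC_MSH - BIC_MIH; delta_supp_null_printed =
# printed BIC of the supported directional model minus the null-model BIC;
# fisher_c = printed Fisher's C of the supported model (single claim, df 2);
# misfit_printed = the printed P<0.05 asterisk; null_flag_printed = the printed
# missing-path footnote marking regions where the null model prevailed.
country,region,region_code,n,bic_msh,bic_mih,bic_null,delta_bic_printed,delta_supp_null_printed,fisher_c,misfit_printed,null_flag_printed
Russia,Kola,RU,28,38.779,38.65,35.729,0.129,2.921,2.407,False,True
US,Sequoia National Park,US(SE),132,59.903,62.438,94.089,-2.535,-34.186,6.192,True,False
US,Great Canyon National Park,US(GC),229,94.24,83.382,161.567,10.858,-78.185,7.31,True,False
Sweden,Northern Sweden,SW,101,61.954,51.06,127.12,10.894,-76.06,0.294,False,False
Spain,Sierra Nevada National Park,SP1,56,46.133,47.261,57.43,-1.128,-11.297,1.854,False,False
Switzerland,Alps,CH,234,80.669,77.006,75.72,3.663,1.286,0.507,False,True
Bhutan,Toepisa,BH,160,75.803,76.021,177.499,-0.217,-101.696,4.751,False,False
US,Alaska,US(AL),491,96.893,88.159,248.759,8.734,-160.6,1.409,False,False
US,New York,US(NY),197,75.841,75.445,101.421,0.396,-25.976,1.48,False,False
Brazil,Bahia,BR,106,61.503,51.564,66.877,9.939,-15.313,0.266,False,False
Ecuador,Western Ecuador,EC,48,44.902,43.462,68.355,1.44,-24.893,0.879,False,False
Australia,Victoria,AU,44,46.95,42.955,46.344,3.995,-3.389,1.329,False,False
France,Mercantour National Park,FR2,61,45.302,51.407,56.684,-6.105,-11.382,0.082,False,False
Chile,Northern Patagonia,CL,109,71.179,71.031,118.788,0.148,-47.757,5.352,False,False
France,Cevennes National Park,FR1,98,51.299,51.419,47.123,-0.12,4.176,1.273,False,True
Spain,Fuentes Carrionas Natural Park,SP2,117,55.627,60.421,57.464,-4.794,-1.837,3.243,False,False
US,Klamath Forest,US(CA),74,48.697,47.473,89.029,1.224,-41.556,0.128,False,False
Ecuador,Podocarpus National Park,EC(PO),30,37.992,42.404,43.511,-4.412,-5.519,0.579,False,False
Peru,Rio Abiseo National Park,PE,30,40.796,50.038,49.742,-9.242,-8.946,3.383,False,False
Myanmar,Wetphuyay,MY,62,59.836,58.427,103.986,1.409,-45.559,0.647,False,False
Uganda,National Park,UG,622,106.037,116.223,663.936,-10.186,-557.899,5.506,False,False
Bolivia,Madidi National Park,BO,44,54.454,71.85,76.687,-17.396,-22.233,1.475,False,False
Costa Rica,Costa Rica,CR,96,69.109,72.112,120.279,-3.003,-51.17,5.208,False,False
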