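map_name,statistic,p_raw,p_fdr,significant
ttp,9,0.1,0.16,False
dsovers,9,0.1,0.16,False
ms,8,0.2,0.2666666667,False
cbv_auc,9,0.1,0.16,False
cbf_ssvd,9,0.1,0.16,False
cbv_ssvd,9,0.1,0.16,False
mtt_ssvd,2,0.4,0.4571428571,False
tmax_ssvd,3,1,1,False
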