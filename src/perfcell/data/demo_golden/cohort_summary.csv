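map_name,mask_name,n_animals,rho_mean,rho_sd,adj_r2_mean,adj_r2_sd
cbf_ssvd,accumulation,5,0.3156596455,0.1830353463,0.1407480888,0.1265736804
cbf_ssvd,whole_brain,5,0.3029687074,0.1739428913,0.1373284255,0.1190119329
cbv_auc,accumulation,6,0.3196470367,0.1366731145,0.1393626514,0.1223413605
cbv_auc,whole_brain,6,0.351916564,0.1487001051,0.1431285043,0.1181507594
cbv_ssvd,accumulation,6,0.316958367,0.1389973677,0.1388649703,0.1217154441
cbv_ssvd,whole_brain,6,0.3494986664,0.1527811861,0.1427300799,0.1180201439
dsovers,accumulation,6,0.3355153277,0.164722466,0.1551760208,0.1369209396
dsovers,whole_brain,6,0.3648397317,0.1424994984,0.1560926388,0.127448303
ms,accumulation,4,0.2338467415,0.1453027238,0.06983486224,0.07224510721
ms,whole_brain,5,0.2130075556,0.1231913968,0.05577620097,0.06316199911
mtt_ssvd,accumulation,4,-0.1550215581,0.1830696714,0.04169403334,0.03716812673
mtt_ssvd,whole_brain,4,-0.1245880923,0.06243854649,0.02553509,0.02451730216
ttp,accumulation,4,0.1485530266,0.06727443429,0.05041379093,0.0353507704
ttp,whole_brain,3,0.2021601963,0.03578316074,0.0503605101,0.03351100055
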