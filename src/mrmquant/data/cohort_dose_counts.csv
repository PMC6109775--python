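analyte,visit,dose_mg,n_eligible,n_above_lloq,median,q1,q3
ATV,M1,40,44,43,4.86,1.92,9.53
ATV,M1,80,674,631,5.67,3.19,10.98
2-OH ATV,M1,40,44,42,5.85,2.80,8.81
2-OH ATV,M1,80,674,640,7.49,4.26,12.76
ATV L,M1,40,44,31,3.98,2.51,8.90
ATV L,M1,80,674,569,4.94,2.87,9.41
2-OH ATV L,M1,40,44,42,4.64,2.74,9.73
2-OH ATV L,M1,80,674,644,7.49,4.39,13.22
BSP,M1,1.25,141,140,5.67,4.31,7.63
BSP,M1,2.5,320,316,10.83,8.24,14.05
BSP,M1,3.75,21,21,17.50,12.53,23.05
BSP,M1,5,174,167,23.14,17.08,28.86
BSP,M1,6.25,2,2,55.34,,
BSP,M1,7.5,25,24,36.74,27.35,45.67
BSP,M1,10,50,49,43.93,28.06,52.73
BSP,M1,20,3,3,105.49,,
CLP-CA,M1,75,811,792,736.94,392.13,1211.11
ATV,M12,80,173,157,4.97,2.81,8.48
2-OH ATV,M12,80,173,163,7.48,3.86,11.42
ATV L,M12,80,173,131,4.33,2.71,7.46
2-OH ATV L,M12,80,173,165,6.63,4.07,9.86
BSP,M12,1.25,27,26,5.50,4.28,7.05
BSP,M12,2.5,83,83,10.27,6.78,13.67
BSP,M12,3.75,6,6,13.34,10.13,18.27
BSP,M12,5,50,49,20.32,15.50,30.68
BSP,M12,6.25,1,1,58.7,,
BSP,M12,7.5,4,4,32.38,12.70,51.56
BSP,M12,10,11,10,53.37,37.17,68.51
BSP,M12,20,1,1,167.2,,
CLP-CA,M12,75,205,195,737.58,414.61,1124.49
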