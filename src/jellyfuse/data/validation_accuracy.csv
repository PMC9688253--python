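classifier,dataset,strategy,dim_fused,acc_fused,dim_ranked,acc_ranked
dt,HAM 10000,CFS,2560,0.9110,2560,0.9110
dt,HAM 10000,AWFS,2560,0.9124,512+1024,0.9410
dt,HAM 10000,MOWFS-GA,2560,0.9116,512,0.9411
dt,HAM 10000,MOWFS-PSO,2560,0.9215,512,0.9412
dt,HAM 10000,MOWFS-AJS,2560,0.9219,1024,0.9401
dt,HAM 10000,FOWFS-GA,2560,0.9310,1015,0.9312
dt,HAM 10000,FOWFS-PSO,2560,0.9322,954,0.9412
dt,HAM 10000,FOWFS-AJS,2560,0.9322,914,0.9422
dt,BCN 20000,CFS,2560,0.8847,2560,0.8847
dt,BCN 20000,AWFS,2560,0.8925,512,0.9610
dt,BCN 20000,MOWFS-GA,2560,0.8948,512+1024,0.9611
dt,BCN 20000,MOWFS-PSO,2560,0.9012,512+1024+1024,0.9612
dt,BCN 20000,MOWFS-AJS,2560,0.8999,1121,0.9602
dt,BCN 20000,FOWFS-GA,2560,0.9015,998,0.9512
dt,BCN 20000,FOWFS-PSO,2560,0.9128,1019,0.9611
dt,BCN 20000,FOWFS-AJS,2560,0.9198,925,0.9622
nb,HAM 10000,CFS,2560,0.9118,2560,0.9118
nb,HAM 10000,AWFS,2560,0.9211,512,0.9411
nb,HAM 10000,MOWFS-GA,2560,0.9124,512,0.9421
nb,HAM 10000,MOWFS-PSO,2560,0.9158,1024,0.9422
nb,HAM 10000,MOWFS-AJS,2560,0.9199,1024+1024,0.9428
nb,HAM 10000,FOWFS-GA,2560,0.9210,995,0.9391
nb,HAM 10000,FOWFS-PSO,2560,0.9214,961,0.9438
nb,HAM 10000,FOWFS-AJS,2560,0.9218,1015,0.9448
nb,BCN 20000,CFS,2560,0.9001,2560,0.9001
nb,BCN 20000,AWFS,2560,0.9191,512+1024,0.9611
nb,BCN 20000,MOWFS-GA,2560,0.9125,1024,0.9621
nb,BCN 20000,MOWFS-PSO,2560,0.9215,512+1024,0.9622
nb,BCN 20000,MOWFS-AJS,2560,0.9244,512+1024+1024,0.9628
nb,BCN 20000,FOWFS-GA,2560,0.9248,1115,0.9594
nb,BCN 20000,FOWFS-PSO,2560,0.9314,1245,0.9632
nb,BCN 20000,FOWFS-AJS,2560,0.9325,998,0.9648
mlp,HAM 10000,CFS,2560,0.9211,2560,0.9211
mlp,HAM 10000,AWFS,2560,0.9214,1024,0.9550
mlp,HAM 10000,MOWFS-GA,2560,0.9244,512+1024,0.9552
mlp,HAM 10000,MOWFS-PSO,2560,0.9214,512+1024,0.9558
mlp,HAM 10000,MOWFS-AJS,2560,0.9254,512,0.9561
mlp,HAM 10000,FOWFS-GA,2560,0.9311,915,0.9342
mlp,HAM 10000,FOWFS-PSO,2560,0.9324,898,0.9537
mlp,HAM 10000,FOWFS-AJS,2560,0.9345,975,0.9562
mlp,BCN 20000,CFS,2560,0.9112,2560,0.9112
mlp,BCN 20000,AWFS,2560,0.9119,512+1024,0.9650
mlp,BCN 20000,MOWFS-GA,2560,0.9132,1024+1024,0.9652
mlp,BCN 20000,MOWFS-PSO,2560,0.9124,512,0.9658
mlp,BCN 20000,MOWFS-AJS,2560,0.9312,512+1024,0.9661
mlp,BCN 20000,FOWFS-GA,2560,0.9365,1124,0.9549
mlp,BCN 20000,FOWFS-PSO,2560,0.9378,954,0.9649
mlp,BCN 20000,FOWFS-AJS,2560,0.9411,929,0.9669
svm,HAM 10000,CFS,2560,0.9225,2560,0.9225
svm,HAM 10000,AWFS,2560,0.9315,1024+1024,0.9599
svm,HAM 10000,MOWFS-GA,2560,0.9311,512,0.9611
svm,HAM 10000,MOWFS-PSO,2560,0.9347,512+1024,0.9712
svm,HAM 10000,MOWFS-AJS,2560,0.9348,512+1024,0.9612
svm,HAM 10000,FOWFS-GA,2560,0.9378,1125,0.9479
svm,HAM 10000,FOWFS-PSO,2560,0.9399,897,0.9679
svm,HAM 10000,FOWFS-AJS,2560,0.9425,867,0.9779
svm,BCN 20000,CFS,2560,0.9147,2560,0.9147
svm,BCN 20000,AWFS,2560,0.9110,1024,0.9599
svm,BCN 20000,MOWFS-GA,2560,0.9118,1024+512,0.9611
svm,BCN 20000,MOWFS-PSO,2560,0.9210,1024+1024,0.9712
svm,BCN 20000,MOWFS-AJS,2560,0.9211,512,0.9612
svm,BCN 20000,FOWFS-GA,2560,0.9212,1005,0.9579
svm,BCN 20000,FOWFS-PSO,2560,0.9245,905,0.9688
svm,BCN 20000,FOWFS-AJS,2560,0.9311,899,0.9779
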