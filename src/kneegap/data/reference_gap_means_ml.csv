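pose,method,group,medial,lateral,printed_imbalance,reconciles
extension,all,varus,9.8,17.5,7.7,true
extension,all,valgus,13.1,14.0,0.5,false
flexion,TEA,varus,10.2,16.6,6.4,true
flexion,TEA,valgus,13.3,15.9,2.6,true
flexion,PCA,varus,10.2,16.2,6.0,true
flexion,PCA,valgus,13.4,15.4,2.0,true
flexion,WSL,varus,10.2,15.7,5.5,true
flexion,WSL,valgus,13.1,14.3,1.2,true
flexion,FEA,varus,9.5,17.6,8.0,false
flexion,FEA,valgus,12.8,16.4,3.6,true
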