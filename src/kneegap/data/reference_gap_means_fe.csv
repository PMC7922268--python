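method,group,compartment,extension,flexion,printed_delta,reconciles
TEA,varus,medial,9.8,10.2,-0.4,true
TEA,varus,lateral,17.5,16.6,0.8,false
TEA,valgus,medial,13.1,13.3,-0.2,true
TEA,valgus,lateral,14.2,15.7,-1.5,true
PCA,varus,medial,9.8,10.2,-0.4,true
PCA,varus,lateral,17.5,16.2,1.2,false
PCA,valgus,medial,13.1,13.4,-0.3,true
PCA,valgus,lateral,14.2,15.4,-1.2,true
WSL,varus,medial,9.8,10.2,-0.3,false
WSL,varus,lateral,17.5,15.6,1.8,false
WSL,valgus,medial,13.1,13.1,0.0,true
WSL,valgus,lateral,14.2,14.3,-0.1,true
FEA,varus,medial,9.8,9.5,0.3,true
FEA,varus,lateral,17.5,17.6,-0.1,true
FEA,valgus,medial,13.1,12.8,0.3,true
FEA,valgus,lateral,14.2,16.4,-2.2,true
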