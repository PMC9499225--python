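subfamily,genus,species_group,species,role,brightness_mean,brightness_n,relative_eye_size,type_locality
Dolichoderinae,Dorymyrmex,,ensifer,candidate,72.5,2,0.0331,ARGENTINA
Dolichoderinae,Dorymyrmex,,ensifer laevigatus,candidate,72.7,1,0.0323,ARGENTINA
Dolichoderinae,Dorymyrmex,,ensifer weiseri,candidate,72.0,1,0.0340,ARGENTINA
Dolichoderinae,Dorymyrmex,,exsanguinus,candidate,71.3,3,0.0370,ARGENTINA
Dolichoderinae,Dorymyrmex,,exsanguinus anaemicus,candidate,76.3,1,0.0384,ARGENTINA
Dolichoderinae,Dorymyrmex,,morenoi patagon,candidate,85.3,1,0.0344,ARGENTINA
Dolichoderinae,Dorymyrmex,,nr. morenoi,candidate,72.3,1,0.0383,ARGENTINA
Dolichoderinae,Dorymyrmex,,dark congeners,dark_reference,,,0.0249,
Dolichoderinae,Iridomyrmex,,macrops,candidate,73.7,1,0.0341,AUSTRALIA
Dolichoderinae,Iridomyrmex,,dark congeners,dark_reference,,,0.0278,
Myrmicinae,Temnothorax,laurae,arenarius,candidate,81.2,2,0.0383,TUNISIA
Myrmicinae,Temnothorax,laurae,arenarius fusciventris,candidate,78.7,1,0.0353,TUNISIA
Myrmicinae,Temnothorax,laurae,canescens,candidate,73.3,1,0.0246,SPAIN
Myrmicinae,Temnothorax,laurae,laciniatus,candidate,75.3,1,0.0288,ALGERIA
Myrmicinae,Temnothorax,laurae,laurae,candidate,72.7,1,0.0273,TUNISIA
Myrmicinae,Temnothorax,laurae,laurae rosae,candidate,77.0,1,0.0314,TUNISIA
Myrmicinae,Temnothorax,laurae,megalops,candidate,72.3,1,0.0267,SUDAN
Myrmicinae,Temnothorax,laurae,mpala,candidate,73.0,1,0.0261,KENYA
Myrmicinae,Temnothorax,laurae,naeviventris,candidate,73.4,3,0.0330,TUNISIA
Myrmicinae,Temnothorax,laurae,naeviventris kefensis,candidate,74.0,1,0.0243,TUNISIA
Myrmicinae,Temnothorax,tricarinatus,bestelmeyeri,candidate,75.0,1,0.0303,USA
Myrmicinae,Temnothorax,tricarinatus,coleenae,candidate,78.0,1,0.0286,USA
Myrmicinae,Temnothorax,tricarinatus,liebi,candidate,83.3,1,0.0291,USA
Myrmicinae,Temnothorax,tricarinatus,dark congeners,dark_reference,,,0.0224,
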