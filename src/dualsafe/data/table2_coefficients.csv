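number,path_id,coefficient
1,ST->SCA,0.74
2,IM->SM,0.128
3,SCA->SB,0.217
4,SCO->SB,0.207
5,SM->SB,0.440
6,USPH->SB,-0.012
7,USPS->SB,-0.086
8,WE->SB,-0.038
9,SCL->SCO,0.619
10,SCU->SCO,0.381
11,PH->USPH,0.466
12,PF->USPH,0.534
13,WP->USPS,0.605
14,LP->USPS,0.395
15,PW->WE,0.527
16,WI->WE,0.473
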