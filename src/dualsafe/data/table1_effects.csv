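path_id,study_id,n,effect_kind,effect_value,df
ST->SCA,s01,267,r,0.74,
SCL->SCO,s02,256,r,0.443,
SCL->SCO,s03,257,r,0.37,
SCU->SCO,s04,297,r,0.437,
IM->SM,s05,259,r,0.108,
IM->SM,s06,259,r,0.15,
SCA->SB,s07,304,r,0.636,
SCA->SB,s08,304,r,0.301,
SCA->SB,s09,305,r,0.56,
SCA->SB,s10,305,r,0.301,
SCA->SB,s11,305,r,0.12,
SCO->SB,s12,330,r,0.423,
SCO->SB,s13,330,r,0.698,
SCO->SB,s14,331,r,0.19,
SCO->SB,s15,331,r,0.19,
SM->SB,s16,301,r,0.416,
SM->SB,s17,301,r,0.567,
SM->SB,s18,302,r,0.355,
SM->SB,s19,302,r,0.796,
SM->SB,s20,302,r,0.271,
SM->SB,s21,302,r,0.537,
SM->SB,s22,302,r,0.31,
SM->SB,s23,302,r,0.14,
USPH->SB,s24,267,r,-0.14,
USPS->SB,s25,267,r,-0.387,
USPS->SB,s26,267,r,-0.332,
USPS->SB,s27,267,r,-0.24,
WE->SB,s28,331,r,-0.292,
WE->SB,s29,331,r,-0.11,
PH->USPH,s30,282,r,0.54,
PH->USPH,s31,282,r,0.710,
PF->USPH,s32,282,r,0.77,
PF->USPH,s33,282,r,0.697,
WP->USPS,s34,268,r,0.644,
WP->USPS,s35,269,r,0.48,
WP->USPS,s36,269,r,0.742,
LP->USPS,s37,267,r,0.40,
LP->USPS,s38,267,r,0.734,
PW->WE,s39,373,r,0.55,
PW->WE,s40,374,r,0.67,
WI->WE,s41,373,r,0.58,
WI->WE,s42,374,r,0.56,
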