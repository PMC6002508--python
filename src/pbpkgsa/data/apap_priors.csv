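name,family,loc,spread,trunc_z,units,subset
Tg,truncated-lognormal,0.23,0.5,3,h,original
Tp,truncated-lognormal,0.033,0.5,3,h,original
CYP_Km,truncated-lognormal,130,1,1,uM,original
CYP_VmaxC,uniform,0.14,2900,,umol/h/BW^0.75,original
SULT_Km_apap,truncated-lognormal,300,1,1,uM,original
SULT_Ki,truncated-lognormal,526,0.5,2,uM,original
SULT_Km_paps,truncated-lognormal,0.5,0.5,2,-,original
SULT_VmaxC,uniform,1,3.26e6,,umol/h/BW^0.75,original
UGT_Km,truncated-lognormal,6.0e3,1,1,uM,original
UGT_Ki,truncated-lognormal,5.8e4,0.5,2,uM,original
UGT_Km_GA,truncated-lognormal,0.5,0.5,2,-,original
UGT_VmaxC,uniform,1,3.26e6,,umol/h/BW^0.75,original
Km_AG,truncated-lognormal,1.99e4,0.3,3,uM,original
Vmax_AG,uniform,1.09e3,3.26e6,,umol/h,original
Km_AS,truncated-lognormal,2.99e4,0.22,3,uM,original
Vmax_AS,uniform,1.09e3,3.26e6,,umol/h,original
kGA_syn,uniform,1,4.43e5,,1/h,original
kPAPS_syn,uniform,1,4.43e5,,1/h,original
CLC_APAP,uniform,2.48e-3,2.718,,L/h/BW^0.75,original
CLC_AG,uniform,2.48e-3,2.718,,L/h/BW^0.75,original
CLC_AS,uniform,2.48e-3,2.718,,L/h/BW^0.75,original
QCC,truncated-lognormal,16.2,0.2,4,L/h/BW^0.75,additional
VFC,truncated-lognormal,0.214,0.45,2,-,additional
VKC,truncated-lognormal,0.0044,0.17,2,-,additional
VGC,truncated-lognormal,0.0144,0.08,2,-,additional
VLC,truncated-lognormal,0.0257,0.23,2,-,additional
VMC,truncated-lognormal,0.4,0.34,2,-,additional
VBLAC,truncated-lognormal,0.0243,0.12,2,-,additional
VBLVC,truncated-lognormal,0.0557,0.12,2,-,additional
VSC,truncated-lognormal,0.185,0.34,2,-,additional
QFC,truncated-lognormal,0.052,0.46,2,-,additional
QKC,truncated-lognormal,0.175,0.18,2,-,additional
QGC,truncated-lognormal,0.181,0.45,2,-,additional
QLBC,truncated-lognormal,0.046,0.12,2,-,additional
QMC,truncated-lognormal,0.191,0.32,2,-,additional
QSC,truncated-lognormal,0.14,0.35,2,-,additional
BP_APAP,truncated-lognormal,0.9,0.4,3,-,additional
PF_APAP,truncated-lognormal,0.447,,,-,additional
PG_APAP,truncated-lognormal,0.907,,,-,additional
PK_APAP,truncated-lognormal,0.711,,,-,additional
PL_APAP,truncated-lognormal,0.687,,,-,additional
PM_APAP,truncated-lognormal,0.687,,,-,additional
PR_APAP,truncated-lognormal,0.676,,,-,additional
PS_APAP,truncated-lognormal,0.606,,,-,additional
PF_AS,truncated-lognormal,0.088,,,-,additional
PG_AS,truncated-lognormal,0.297,,,-,additional
PK_AS,truncated-lognormal,0.261,,,-,additional
PL_AS,truncated-lognormal,0.203,,,-,additional
PM_AS,truncated-lognormal,0.199,,,-,additional
PR_AS,truncated-lognormal,0.207,,,-,additional
PS_AS,truncated-lognormal,0.254,,,-,additional
PF_AG,truncated-lognormal,0.128,,,-,additional
PG_AG,truncated-lognormal,0.436,,,-,additional
PK_AG,truncated-lognormal,0.392,,,-,additional
PL_AG,truncated-lognormal,0.321,,,-,additional
PM_AG,truncated-lognormal,0.336,,,-,additional
PR_AG,truncated-lognormal,0.364,,,-,additional
PS_AG,truncated-lognormal,0.351,,,-,additional
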