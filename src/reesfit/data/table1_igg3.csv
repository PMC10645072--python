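allele,group,n_trp,csm_fc_avg,csm_fc_sd,dgm_avg,dgm_sd,csm_r_avg,csm_r_sd,sasa_per_trp
IGHG3*01,IgG3-Arg292,22,353.1,0.2,7.0,0.2,418.9,2.9,4.89
IGHG3*03,IgG3-Arg292,22,352.5,0.2,7.3,0.1,418.9,2.9,4.75
IGHG3*04,IgG3-Arg292,22,353.1,0.2,7.1,0.2,418.9,2.9,7.12
IGHG3*06,IgG3-Arg292,22,353.1,0.9,6.9,0.3,418.9,2.9,6.87
IGHG3*08,IgG3-Arg292,22,352.7,0.2,6.6,0.5,418.9,2.9,6.85
IGHG3*09,IgG3-Arg292,22,352.9,0.0,7.0,0.1,418.9,2.9,10.73
IGHG3*11,IgG3-Arg292,22,352.9,0.1,7.0,0.1,418.9,2.9,6.63
IGHG3*12,IgG3-Arg292,22,352.7,0.4,6.7,0.5,418.9,2.9,8.69
IGHG3*13,IgG3-Arg292,22,352.7,0.2,7.1,0.2,418.9,2.9,10.52
IGHG3*14,IgG3-Arg292,22,353.0,0.4,7.1,0.1,418.9,2.9,8.67
IGHG3*15,IgG3-Arg292,22,353.1,0.4,7.2,0.1,418.9,2.9,8.86
IGHG3*16,IgG3-Arg292,22,353.6,0.6,7.2,0.1,418.9,2.9,11.49
IGHG3*17,IgG3-Arg292,22,352.4,0.2,6.6,0.3,418.9,2.9,8.86
IGHG3*20,IgG3-Arg292,22,353.2,0.2,6.8,0.3,418.9,2.9,8.45
IGHG3*22,IgG3-Arg292,22,352.9,0.3,6.9,0.3,418.9,2.9,7.07
IGHG3*24,IgG3-Arg292,22,352.9,0.2,7.1,0.1,418.9,2.9,6.93
IGHG3*25,IgG3-Arg292,22,353.1,0.1,7.3,0.1,418.9,2.9,8.06
IGHG3*26,IgG3-Arg292,22,352.7,0.1,7.1,0.1,418.9,2.9,8.75
IGHG3*18,IgG3-Trp292,24,353.7,0.2,7.7,0.3,423.3,16.2,21.27
IGHG3*19,IgG3-Trp292,24,354.2,0.2,8.0,0.2,423.3,16.2,15.91
IGHG3*23,IgG3-Trp292,24,353.9,0.3,7.7,0.1,423.3,16.2,19.24
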