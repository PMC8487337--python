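label,population,arm,endpoint,group1,x1,n1,rate1_pct,group2,x2,n2,rate2_pct,direction,printed_diff,printed_ci_low,printed_ci_high,method_diff,method_ci_low,method_ci_high,tag,provenance
acm_itt_ct,ITT,ceftolozane/tazobactam,mortality_day28,ARC,17,96,17.7,normal,23,131,17.6,ARC_minus_normal,0.2,-9.6,10.6,0.2,-9.6,10.6,recovered,trial report abstract and Results (28-day ACM)
acm_itt_meropenem,ITT,meropenem,mortality_day28,ARC,20,113,17.7,normal,25,123,20.3,ARC_minus_normal,-2.6,-12.6,7.5,-2.6,-12.6,7.5,recovered,trial report abstract and Results (28-day ACM)
clinical_cure_itt_ct,ITT,ceftolozane/tazobactam,clinical_cure_toc,normal,75,131,57.3,ARC,57,96,59.4,normal_minus_ARC,-2.1,-14.8,10.8,-2.1,-14.7,10.8,recovered,trial report abstract and Results (clinical cure at TOC); published lower bound -14.8 is not consistent with method 10 at any counts matching the published rates
clinical_cure_itt_meropenem,ITT,meropenem,clinical_cure_toc,normal,73,123,59.3,ARC,65,113,57.5,normal_minus_ARC,1.8,-10.6,14.2,1.8,-10.6,14.2,recovered,trial report abstract and Results (clinical cure at TOC)
micro_cure_mitt_ct,mITT,ceftolozane/tazobactam,micro_cure_toc,normal,70,97,72.2,ARC,55,77,71.4,normal_minus_ARC,0.7,-12.4,14.2,0.7,-12.4,14.2,printed,trial report abstract (microbiologic cure n/N printed)
micro_cure_mitt_meropenem,mITT,meropenem,micro_cure_toc,normal,66,88,75.0,ARC,49,70,70.0,normal_minus_ARC,5.0,-8.7,19.0,5.0,-8.7,19.0,printed,trial report abstract (microbiologic cure n/N printed)
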