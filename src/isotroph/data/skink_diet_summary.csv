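species,major_prey,major_prey_proportion,major_prey_rank,other_prey_mean_rank,weighted_trophic_rank,mean_d15N_lorna_glen,mean_d15N_yamarna
Lerista bipes,Isoptera,0.48,2,3.1,2.5,7.88,7.62
Ctenotus calurus,Isoptera,0.14,2,2.1,2.0,8.77,6.26
Ctenotus dux,Isoptera,0.57,2,2.6,2.3,10.22,8.23
Ctenotus grandis,Vertebrates,0.72,5,3.0,3.3,,9.4
Ctenotus inornatus,Isoptera,0.55,2,2.6,2.1,10.02,10.09
Ctenotus pantherinus,Isoptera,0.10,2,3.2,2.1,9.51,7.02
Ctenotus piankai,Pentatomidae,0.79,2,2.3,2.3,,8.78
Ctenotus quattuordecimlineatus,Isoptera,0.75,2,2.5,2.2,13.09,9.42
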