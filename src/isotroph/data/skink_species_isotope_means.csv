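site,species,mean_d15N,mean_d13C,range_d15N,range_d13C
Yamarna,Ctenotus calurus,6.26,-17.42,4.24,7.45
Yamarna,Ctenotus dux,8.23,-18.47,2.54,2.81
Yamarna,Ctenotus grandis,9.4,-17.96,1.92,5.07
Yamarna,Ctenotus inornatus,10.09,-19.24,4.22,1.87
Yamarna,Ctenotus leae,8.47,-22.54,3.90,4.93
Yamarna,Ctenotus pantherinus,7.02,-15.86,5.40,3.46
Yamarna,Ctenotus piankai,8.78,-17.42,2.64,3.31
Yamarna,Ctenotus quattuordecimlineatus,9.42,-18.59,3.42,3.51
Yamarna,Ctenotus brooksi,9.56,-21.75,2.60,4.62
Yamarna,Eremiascincus fasciolatus,7.77,-20.56,1.74,1.62
Yamarna,Lerista bipes,7.62,-18.79,5.11,7.17
Yamarna,Lerista desertorum,11.61,-22.25,4.68,1.37
Lorna Glen,Ctenotus calurus,8.77,-17.33,5.48,4.33
Lorna Glen,Ctenotus dux,10.22,-21.46,0.81,2.50
Lorna Glen,Ctenotus inornatus,10.02,-18.10,3.54,6.91
Lorna Glen,Ctenotus leonhardii,12.91,-19.28,2.56,3.55
Lorna Glen,Ctenotus pantherinus,9.51,-16.85,3.42,5.61
Lorna Glen,Ctenotus quattuordecimlineatus,13.09,-18.30,2.88,8.39
Lorna Glen,Ctenotus schomburgkii,15.48,-20.03,0.68,4.68
Lorna Glen,Lerista bipes,7.88,-19.98,2.13,5.32
Lorna Glen,Lerista desertorum,12.39,-19.85,5.82,9.52
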