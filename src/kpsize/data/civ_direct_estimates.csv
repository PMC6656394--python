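area_id,method_label,n_hat,ci_low,ci_high
Abidjan,ngo,3535,2593,5550
Abidjan,ngo_2,2334,1773,3415
Abidjan,service,2759,2083,4087
Abidjan,social_event,2334,1669,3879
Abidjan,unique_object,1910,1412,2947
Agboville,ngo,1015,807,1369
Agboville,social_event,480,351,760
Agboville,unique_object,823,599,1315
Bouake,ngo,3873,2536,8190
Bouake,service,747,600,988
Bouake,social_event,473,397,586
Bouake,unique_object,831,708,1006
Gagnoa,service,947,628,1925
Gagnoa,social_event,384,287,581
Gagnoa,unique_object,555,409,860
Yamoussoukro,ngo,1036,721,1835
Yamoussoukro,service,1688,1038,4517
Yamoussoukro,social_event,398,300,589
Yamoussoukro,unique_object,983,754,1412
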