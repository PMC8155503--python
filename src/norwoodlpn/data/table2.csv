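study_id,parameter,stage,n,value_form,center,dispersion,range_low,range_high
b30,age,healthy,7,value_only,5,,,
b30,descending_aorta_diameter,healthy,7,mean_sd,6.7,0.8,,
b40,lpa_diameter,healthy,813,value_only,4.6,,,
b40,rpa_diameter,healthy,813,value_only,4.9,,,
b40,descending_aorta_diameter,healthy,813,value_only,6.1,,,
b33,age,post_s1,50,median_range,19.9,,2,46
b33,bsa,post_s1,50,mean_sd,0.23,0.02,,
b33,transverse_arch_diameter,post_s1,50,mean_sd,11.6,0.22,,
b37,age,post_s1,31,mean_sd,13.9,8.4,,
b37,systolic_pressure,post_s1,31,value_only,77,,,
b37,diastolic_pressure,post_s1,31,value_only,39,,,
b32,age,post_s1,22,value_only,5,,,
b32,systolic_pressure,post_s1,22,mean_sd,78.2,8.4,,
b32,diastolic_pressure,post_s1,22,mean_sd,38.4,4.4,,
b36,age,post_s1,18,value_only,10.44,,,
b36,systolic_pressure,post_s1,18,median_range,62.8,,57.5,72
b36,diastolic_pressure,post_s1,18,median_range,37.3,,32,41
b46,systolic_pressure,post_s1,24,mean_sd,78,11,,
b46,diastolic_pressure,post_s1,24,mean_sd,37,7,,
b46,qp_qs,post_s1,24,mean_sd,1.7,1.0,,
b11,age,post_s1,37,median_range,4,,2,17
b11,systolic_pressure,post_s1,37,mean_sd,64,7,,
b11,diastolic_pressure,post_s1,37,value_only,36.5,,,
b11,mean_pressure,post_s1,37,value_only,47,,,
b17,age,post_s1,117,mean_sd,7.2,6.5,,
b17,mean_pressure,post_s1,117,mean_sd,51,6,,
b17,qp_qs,post_s1,117,mean_sd,1.7,0.9,,
b41,age,post_s1,20,mean_sd,4.5,3.6,,
b41,systolic_pressure,post_s1,20,value_only,76.5,,,
b41,diastolic_pressure,post_s1,20,value_only,39,,,
b41,mean_pressure,post_s1,20,value_only,52.3,,,
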