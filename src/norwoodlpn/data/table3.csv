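study_id,parameter,stage,n,value_form,center,dispersion,range_low,range_high
b1,age,pre_s2,170,mean_sd,4.5,1.5,,
b1,diastolic_pressure,pre_s2,170,mean_sd,35,7,,
b1,mean_pa_pressure,pre_s2,170,median_range,14,,13,17
b1,qp_qs,pre_s2,170,median_range,1.1,,0.8,1.5
b1,bsa,pre_s2,170,mean_sd,0.31,0.04,,
b1,lpa_diameter,pre_s2,170,median_range,4.8,,4.0,6.0
b1,rpa_diameter,pre_s2,170,median_range,5,,4.0,6.1
b6,age,pre_s2,58,mean_sd,5.28,2.16,,
b6,cardiac_index,pre_s2,58,mean_sd,5.5,2.0,,
b6,lpa_diameter,pre_s2,58,mean_sd,6.01,5.83,,
b6,rpa_diameter,pre_s2,58,mean_sd,8.1,5.5,,
b6,ascending_aorta_diameter,pre_s2,58,mean_sd,14.51,7.82,,
b6,transverse_arch_diameter,pre_s2,58,mean_sd,12.96,7.7,,
b6,descending_aorta_diameter,pre_s2,58,mean_sd,8.04,5.1,,
b5,age,pre_s2,78,median_range,6.23,,2.67,16.3
b5,systolic_pressure,pre_s2,78,median_range,91,,68,135
b5,diastolic_pressure,pre_s2,78,median_range,40,,20,57
b5,mean_pa_pressure,pre_s2,78,median_range,15,,8,22
b5,qp_qs,pre_s2,78,median_range,1.6,,0.47,4.6
b5,bsa,pre_s2,78,mean_sd,0.31,0.04,,
b5,lpa_diameter,pre_s2,78,median_range,5.8,,2.7,11.8
b5,rpa_diameter,pre_s2,78,median_range,6.2,,2.7,12.3
b37,age,pre_s2,31,mean_sd,6.04,1.0,,
b37,systolic_pressure,pre_s2,31,mean_sd,108,14.6,,
b37,diastolic_pressure,pre_s2,31,mean_sd,51.6,9.5,,
b37,qp_qs,pre_s2,31,mean_sd,1.41,0.7,,
b32,age,pre_s2,22,value_only,4.8,,,
b32,mean_pa_pressure,pre_s2,22,median_range,11,,8,16
b32,qp_qs,pre_s2,22,median_range,0.9,,0.4,1.6
b36,age,pre_s2,10,value_only,3,,,
b36,mean_pa_pressure,pre_s2,10,median_range,14,,14,17
b36,qp_qs,pre_s2,10,median_range,1.6,,1.2,1.6
b31,age,pre_s2,10,value_only,5.2,,,
b31,systolic_pressure,pre_s2,10,mean_sd,105.8,14.9,,
b31,diastolic_pressure,pre_s2,10,mean_sd,41.5,10.9,,
b31,mean_pa_pressure,pre_s2,10,mean_sd,16.6,3.74,,
b31,qp_qs,pre_s2,10,mean_sd,1.42,0.36,,
b15,age,pre_s2,19,mean_sd,5,1.0,,
b15,systolic_pressure,pre_s2,19,mean_sd,103,14,,
b15,diastolic_pressure,pre_s2,19,mean_sd,46,14,,
b15,lpa_diameter,pre_s2,19,mean_sd,7.6,3.7,,
b15,rpa_diameter,pre_s2,19,mean_sd,6.3,4.5,,
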