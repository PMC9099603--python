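aviary_id,bird_id,sex,tarsus_mm,reinf_per_day_mean,reinf_per_day_sd,masses_per_day_mean,masses_per_day_sd,dawn_mass_mean,dawn_mass_sd,noon_mass_mean,noon_mass_sd,dusk_mass_mean,dusk_mass_sd,daily_gain_mean,daily_gain_sd,nightly_loss_mean,nightly_loss_sd
114,P77,F,28.8,243,47,71,20,76.3,1.6,80.1,0.9,81.4,1.4,5.1,1.8,5.0,1.7
114,P92,F,30.5,145,44,44,17,75.2,2.2,79.6,1.4,81.5,2.3,6.3,3.0,6.4,3.9
114,P95,F,29.0,358,65,127,40,72.1,1.8,77.1,2.0,77.8,2.7,5.6,2.9,6.0,1.9
114,P78,M,29.4,348,68,41,10,71.1,1.1,75.9,1.5,76.1,1.7,5.0,1.9,4.9,2.3
114,P80,M,29.9,349,56,69,14,91.4,1.1,94.4,1.3,95.0,2.1,3.6,2.2,3.8,2.0
114,P93,M,30.5,129,23,25,11,85.3,5.2,92.6,1.4,92.1,2.6,6.9,5.8,7.1,6.7
116,P75,F,29.6,140,33,31,11,79.4,1.5,85.2,2.7,85.7,2.3,6.5,2.7,6.3,3.1
116,P91,F,30.5,168,51,81,30,77.9,2.6,83.5,2.3,85.3,2.1,7.4,3.1,7.3,2.9
116,P99,F,28.4,150,38,63,27,76.8,1.6,83.0,1.9,85.1,1.0,8.3,1.5,8.3,1.6
116,P74,M,30.6,568,103,107,38,78.4,2.3,83.1,2.1,84.9,1.5,6.5,2.5,6.4,2.6
116,P79,M,30.9,160,26,42,15,82.0,2.6,86.0,2.3,87.2,2.0,5.2,3.6,5.2,3.0
116,P98,M,31.5,372,81,91,38,84.5,2.6,89.3,2.6,90.5,1.7,6.0,1.5,6.2,2.7
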