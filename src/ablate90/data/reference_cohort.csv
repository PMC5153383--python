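patient,tumor_id,disease,device,activity_gbq,n_sites,durations_s,pre_volume_cm3,post_volume_cm3,pct_volume_change_printed
1,1,HCC,resin,1.30,1,600,124.1,112.9,9.9
2,2a,HCC,resin,1.39,3,600/600/600,270.4,239.7,12.8
2,2b,HCC,resin,1.39,2,600/600,241.3,217.0,11.2
3,3,HCC,resin,1.67,2,600/420,276.4,253.9,8.9
4,4,Cholangiocarcinoma,resin,0.62,2,600/600,100.7,78.1,28.9
5,5,HCC,resin,1.24,2,600/360,374.6,352.9,6.1
6,6,Cholangiocarcinoma,resin,0.92,1,600,44.4,32.5,36.6
7,7,Endometrial,resin,1.14,2,600/600,203.2,177.7,14.4
8,8,HCC,resin,1.01,2,220/220,220.9,212.2,4.1
9,9,HCC,resin,1.83,3,600/360/360,213.4,192.7,10.7
10,10,HCC,resin,1.54,1,600,42.5,29.9,42.1
11,11,Breast,resin,1.17,2,260/260,60.2,54.1,11.3
12,12,HCC,glass,2.51,4,600/600/600/600,104.7,82.4,27.1
13,13,HCC,glass,4.13,4,600/600/600/600,323.4,299.1,8.1
14,14,HCC,glass,3.23,2,600/600,258.2,240.1,7.5
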