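patient_id,n_nodules,mode,diam_sum1_cm,diam_sum2_cm,diam_change_percent,diam_response,vol_sum1_cm3,vol_sum2_cm3,vol_change_percent,vol_response
1,4,two_largest,3.2,2.4,-25.0,SD,1.2,0.9,-25.0,SD
1,4,all,4.7,3.9,-17.0,SD,1.4,1.1,-21.4,SD
2,5,two_largest,3.0,2.9,-3.3,SD,1.3,1.3,0.0,SD
2,5,all,5.4,5.6,3.7,SD,1.8,1.9,5.6,SD
3,7,two_largest,3.6,3.7,2.8,SD,1.7,1.7,0.0,SD
3,7,all,7.3,7.2,-1.4,SD,2.3,2.2,-4.3,SD
4,8,two_largest,3.2,2.1,-34.4,PR,0.3,0.5,66.7,SD
4,8,all,7.7,6.9,-10.4,SD,0.9,1.1,22.2,SD
5,8,two_largest,3.3,2.9,-12.1,SD,1.3,1.6,23.1,SD
5,8,all,11.2,11.1,-0.9,SD,4.4,4.8,9.1,SD
6,9,two_largest,6.5,5.8,-10.8,SD,10.6,9.2,-13.2,SD
6,9,all,12.4,12.8,3.2,SD,11.9,11.7,-1.7,SD
7,10,two_largest,4.9,3.7,-24.5,SD,3.6,3.3,-8.3,SD
7,10,all,12.6,14.7,16.7,SD,5.0,7.1,42.0,SD
8,25,two_largest,4.0,4.3,7.5,SD,25.0,26.0,4.0,SD
8,25,all,27.7,31.9,15.2,SD,10.4,15.5,49.0,SD
9,27,two_largest,8.2,8.1,-1.2,SD,23.0,30.1,30.9,SD
9,27,all,45.7,48.0,5.0,SD,46.5,60.2,29.5,SD
10,52,two_largest,7.0,6.9,-1.4,SD,16.5,13.6,-17.6,SD
10,52,all,75.9,79.2,4.3,SD,62.0,59.9,-3.4,SD
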