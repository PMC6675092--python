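patient_id,sex,age,primary_tumor,interval_days,sum1_cm,sum2_cm,change_percent,response
1,F,66,Cholangiocarcinoma,88,2.2,2.2,0.0,SD
2,M,67,RCC,32,1.4,1.4,0.0,SD
3,M,51,"AD, rectal",42,2.6,2.4,-7.7,SD
4,M,74,SCLC,53,4.1,2.9,-29.3,SD
5,M,56,"AD, colon",69,2.9,2.5,-13.8,SD
6,M,71,SCLC,52,6.3,6.2,-1.6,SD
7,M,69,RCC,151,3.3,2.9,-12.1,SD
8,M,73,"AD, colon",54,3.3,3.6,9.1,SD
9,M,74,RCC,88,5.5,5.8,5.5,SD
10,M,68,Maxillary sinus cancer,74,6.2,5.9,-4.8,SD
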