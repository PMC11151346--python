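entry_id,icd_code,display_text,noted_date,overview_text
e01,R91.1,Lung nodule,2019-03-02,incidental finding on CT
e02,C34.90,Lung cancer,2019-09-14,
e03,C44.92,Squamous cell carcinoma of skin,2020-01-20,left forearm
e04,R60.9,Edema,2018-11-05,
e05,I48.91,Atrial fibrillation,2017-06-30,on anticoagulation
e06,J45.909,Asthma,2015-02-11,
e07,J18.9,Community-acquired pneumonia,2021-01-04,resolved
e08,Z79.01,Anticoagulated,2017-07-01,
e09,Q99.9,Chromosomal abnormality unspecified,2016-05-19,
e10,X99.99,Legacy local code,2014-08-23,
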