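characteristic,category,number,percent
gender,Male,16,55.17
gender,Female,13,44.83
staging,I,3,10.34
staging,IIA,6,20.69
staging,IIB,3,10.34
staging,IIIB,11,37.93
staging,IIIC,1,3.45
staging,IV,5,17.25
site,Cecum colon,2,6.90
site,Transverse colon,10,34.48
site,Hepatic flexure,3,10.34
site,Sigmoid colon,8,27.59
site,Rectum,6,20.69
grade,Low (G1),4,13.79
grade,Moderate (G2),19,65.52
grade,High (G3),6,20.69
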