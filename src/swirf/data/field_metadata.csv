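species,abundance_pre,abundance_post_d1,abundance_post_d2,scanned_pre,scanned_post_d1,scanned_post_d2,preservation_days,preservation_months,rh_percent,temp_c,habitat_water,voltinism,max_flight_km,published_group
Ae. cinereus,369,302,264,178,125,118,170,5.6,31.5,21.8,temporary,univoltine,1.60,B
Ae. vexans,74,63,88,66,52,87,229,7.5,30.6,21.7,temporary,multivoltine,5.73,A
An. punctipennis,119,101,95,105,86,85,242,7.9,32.6,22.2,permanent,multivoltine,16.90,D
An. quadrimaculatus,23,16,16,15,15,13,247,8.1,34.4,21.8,permanent,multivoltine,3.42,C
Cq. perturbans,1011,795,1179,121,124,119,229,7.5,32.4,21.9,permanent,univoltine,3.40,A
Cs. melanura,177,108,182,116,109,134,203,6.6,33.2,22.6,permanent,multivoltine,9.80,A
Cx. pipiens/restuans,2391,1723,2570,320,117,115,180,5.9,31.0,22.0,temporary,multivoltine,9.70,D
Oc. abserratus,35,23,22,34,19,21,131,4.3,32.9,22.0,permanent,univoltine,,B
Oc. canadensis,1274,810,794,189,117,115,143,4.7,34.2,21.9,temporary,univoltine,,B
Oc. excrucians,36,16,10,30,9,9,198,6.5,29.6,21.8,permanent,univoltine,10.00,C
Ps. ferox,239,70,126,147,69,121,193,6.3,28.9,21.5,temporary,multivoltine,2.50,D
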