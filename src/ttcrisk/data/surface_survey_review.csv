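area,analytes,n_samples,value_low,value_high,stat_kind,unit,low_censored,source
pharmacy,CP,114,0.0027,0.0055,range,pg_cm2,false,CR18 closed system drug transfer device
pharmacy,CP;IF;MT,219,ND,0.751,median,ng_cm2,,CR19 after refitting laboratory (new technicians)
pharmacy,CP,6,57,110,range,ng_cm2,false,CR20 high cleaning efficacy; printed point value 65 ng/cm2
pharmacy,CP;IF;5-FU,264,0.03,186.8,range,ng_cm2,false,CR21 use of CSTD; means below 2 ng/cm2
pharmacy,CP,75,<0.0015,11,range,ng_cm2,,CR22 no use of CSTD; means below 0.02 ng/cm2
pharmacy,CP;IF;GM,109,<LOD,17.4,mean,ng_cm2,,CR23
pharmacy,CP;Pt,50,5,368,range,pg_cm2,false,CR24 protective measures (contamination and cleaning)
pharmacy,CP,152,3.91,153,p75,pg_cm2,false,CR25 annual setting of goals for surface contamination
pharmacy,CP,193,4.3,81.5,p75,pg_cm2,false,CR26
pharmacy,CP;5-FU,104,0.002,0.018,median,ng_cm2,false,CR27 before use of CSTD
pharmacy,CP,60,0.01,0.06,median,ng_cm2,false,CR28 use of CSTD for 1 and 8 months
pharmacy,CP,248,0.005,0.087,p75,ng_cm2,false,CR29 traces of contamination
pharmacy,PX;DX;IF;CP;5-FU,1541,1.08,1.08,range,ng_cm2,false,CR30 one sample above 1.08; other positives between 0.0108 and 1.08
administration,CP;Pt,50,<0.2,371,range,pg_cm2,,CR24 protective measures (contamination and cleaning)
administration,CP;5-FU;PX,186,0.7,21,range,ug_cm2,false,CR31 insufficient protocols for cleaning
administration,CP;5-FU,104,0.007,0.019,median,ng_cm2,false,CR27 before use of CSTD
administration,CP;IF;GM;5-FU,19479,0.8,236097,range,pg_cm2,false,CR5 development of a monitoring protocol
administration,CP;5-FU,50,0.2,270.24,range,ug_cm2,false,CR32 insufficient protocols for cleaning
administration,CP;5-FU;Pt,120,<LOD,181800,range,pg_cm2,,CR33 personal protective equipment; environmental monitoring
patient_care,CP,56,<0.0015,28,range,ng_cm2,,CR22 no use of CSTD; means below 0.02 ng/cm2
patient_care,CP;IF,724,0.43,23,median,pg_cm2,false,CR34
patient_care,CP;IF,60,0.03,0.15,median,ng_cm2,false,CR35 tube priming in pharmacy
patient_care,CP,143,4.77,159,p75,pg_cm2,false,CR25
patient_care,CP,189,3.5,91.0,p75,pg_cm2,false,CR26 environmental surveillance
patient_care,CP,238,0.0017,0.065,p75,ng_cm2,false,CR29
operating_room,Pt,52,0.22,110000,range,pg_cm2,false,CR36 means below 5.4 pg/cm2
operating_room,Pt,168,0.1,1733,range,pg_cm2,false,CR37 median 0.06-9.42 pg/cm2; safety and cleaning standards
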