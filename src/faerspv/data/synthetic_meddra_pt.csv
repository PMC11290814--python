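pt_code,pt_name,soc_code
10019211,Headache,10029205
10044565,Tremor,10029205
10028813,Nausea,10017947
10012735,Diarrhoea,10017947
10047700,Vomiting,10017947
10018286,Gingival hypertrophy,10017947
10062237,Renal impairment,10038359
10069339,Acute kidney injury,10038359
10020772,Hypertension,10047065
10037660,Pyrexia,10018065
10013709,Drug ineffective,10018065
10053762,Off label use,10022117
10033295,Overdose,10022117
10074829,Biliary anastomosis complication,10022117
10037844,Rash,10040785
10020112,Hirsutism,10040785
10035664,Pneumonia,10021881
10021789,Infection,10021881
10019851,Hepatotoxicity,10019805
10039705,Scleral hyperaemia,10015919
10013774,Dry eye,10015919
10015946,Eye irritation,10015919
10076523,Punctal plug insertion,10042613
10066201,Acute graft versus host disease,10021428
10002034,Anaemia,10005329
10043554,Thrombocytopenia,10005329
10079585,Spermatozoa progressive motility decreased,10022891
10005483,Blood creatinine increased,10022891
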