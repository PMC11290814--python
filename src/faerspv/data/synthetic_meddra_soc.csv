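soc_code,soc_name
10015919,Eye disorders
10022117,"Injury, poisoning and procedural complications"
10021428,Immune system disorders
10021881,Infections and infestations
10038359,Renal and urinary disorders
10029205,Nervous system disorders
10017947,Gastrointestinal disorders
10018065,General disorders and administration site conditions
10040785,Skin and subcutaneous tissue disorders
10022891,Investigations
10019805,Hepatobiliary disorders
10005329,Blood and lymphatic system disorders
10047065,Vascular disorders
10042613,Surgical and medical procedures
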