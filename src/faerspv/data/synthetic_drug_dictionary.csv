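synonym,concept_id
CYCLOSPORINE,RX3008
CICLOSPORIN,RX3008
CYCLOSPORIN,RX3008
CYCLOSPORINE A,RX3008
NEORAL,RX3008
SANDIMMUNE,RX3008
GENGRAF,RX3008
RESTASIS,RX3008
CEQUA,RX3008
TACROLIMUS,RX42316
PROGRAF,RX42316
MYCOPHENOLATE MOFETIL,RX68149
MYCOPHENOLATE,RX68149
CELLCEPT,RX68149
PREDNISONE,RX8640
DELTASONE,RX8640
METHOTREXATE,RX6851
TREXALL,RX6851
ASPIRIN,RX1191
ACETYLSALICYLIC ACID,RX1191
IBUPROFEN,RX5640
ADVIL,RX5640
OMEPRAZOLE,RX7646
PRILOSEC,RX7646
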