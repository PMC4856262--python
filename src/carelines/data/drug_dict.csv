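drug_code,agent_class,category
ONC-FPO-01,FP_oral,other
ONC-FPV-01,FP_iv,other
ONC-OXA-01,oxaliplatin,other
ONC-IRI-01,irinotecan,other
ONC-BEV-01,bevacizumab,other
ONC-CET-01,cetuximab,other
ONC-PAN-01,panitumumab,other
NON-NAR-01,non_oncology,narcotic
NON-COR-01,non_oncology,corticosteroid
NON-DIU-01,non_oncology,diuretic
NON-PPI-01,non_oncology,gi_ppi
NON-ANT-01,non_oncology,antiemetic
NON-OTH-01,non_oncology,other
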