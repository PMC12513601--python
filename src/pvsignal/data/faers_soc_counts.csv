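soc,n_pts,count
Gastrointestinal disorders,65,280
Investigations,61,260
"Injury, poisoning and procedural complications",54,175
General disorders and administration site conditions,48,714
Nervous system disorders,40,98
Cardiac disorders,30,125
Metabolism and nutrition disorders,29,113
Infections and infestations,26,67
Renal and urinary disorders,25,101
"Respiratory, thoracic and mediastinal disorders",22,54
Skin and subcutaneous tissue disorders,22,49
Psychiatric disorders,18,27
Musculoskeletal and connective tissue disorders,17,40
"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",17,24
Vascular disorders,16,31
Product issues,12,16
Surgical and medical procedures,8,12
Eye disorders,7,17
Hepatobiliary disorders,6,8
Ear and labyrinth disorders,5,7
Reproductive system and breast disorders,5,6
Blood and lymphatic system disorders,4,7
Immune system disorders,3,7
Social circumstances,3,5
"Congenital, familial and genetic disorders",2,2
Endocrine disorders,1,1
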