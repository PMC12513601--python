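soc,n_pts,count
Gastrointestinal disorders,63,324
Investigations,71,286
"Injury, poisoning and procedural complications",54,182
General disorders and administration site conditions,57,801
Nervous system disorders,40,115
Cardiac disorders,37,126
Metabolism and nutrition disorders,36,159
Infections and infestations,24,52
Renal and urinary disorders,27,114
"Respiratory, thoracic and mediastinal disorders",20,53
Skin and subcutaneous tissue disorders,30,73
Psychiatric disorders,21,36
Musculoskeletal and connective tissue disorders,18,67
"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",14,20
Vascular disorders,18,39
Product issues,16,24
Surgical and medical procedures,10,22
Eye disorders,6,18
Hepatobiliary disorders,9,10
Ear and labyrinth disorders,4,5
Reproductive system and breast disorders,6,6
Blood and lymphatic system disorders,4,5
Immune system disorders,2,7
Social circumstances,4,8
"Congenital, familial and genetic disorders",1,1
Endocrine disorders,2,2
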