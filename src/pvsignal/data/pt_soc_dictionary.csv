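pt,soc
Death,General disorders and administration site conditions
Drug ineffective,General disorders and administration site conditions
Oedema,General disorders and administration site conditions
Oedema peripheral,General disorders and administration site conditions
Peripheral swelling,General disorders and administration site conditions
Fatigue,General disorders and administration site conditions
Blood potassium increased,Investigations
Blood potassium decreased,Investigations
Blood potassium abnormal,Investigations
Blood sodium increased,Investigations
Weight increased,Investigations
Blood pressure increased,Investigations
Constipation,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Nausea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Abdominal discomfort,Gastrointestinal disorders
Dysphagia,Gastrointestinal disorders
Ileus,Gastrointestinal disorders
Cardiac failure,Cardiac disorders
Cardiac failure congestive,Cardiac disorders
Myocardial infarction,Cardiac disorders
Hypokalaemia,Metabolism and nutrition disorders
Hyperkalaemia,Metabolism and nutrition disorders
Hypernatraemia,Metabolism and nutrition disorders
Fluid overload,Metabolism and nutrition disorders
Renal failure,Renal and urinary disorders
Renal disorder,Renal and urinary disorders
Cerebrovascular accident,Nervous system disorders
Dizziness,Nervous system disorders
Headache,Nervous system disorders
Pneumonia,Infections and infestations
Rash,Skin and subcutaneous tissue disorders
Dyspnoea,"Respiratory, thoracic and mediastinal disorders"
Off label use,"Injury, poisoning and procedural complications"
Product dose omission issue,"Injury, poisoning and procedural complications"
Intentional product misuse,"Injury, poisoning and procedural complications"
Fall,"Injury, poisoning and procedural complications"
Product use issue,Product issues
Insomnia,Psychiatric disorders
Arthralgia,Musculoskeletal and connective tissue disorders
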