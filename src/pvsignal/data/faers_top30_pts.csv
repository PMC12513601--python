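rank,pt,count
1,Death,520
2,Blood potassium increased,81
3,Constipation,56
4,Diarrhoea,41
5,Oedema,37
6,Cardiac failure,31
7,Hypokalaemia,31
8,Drug ineffective,27
9,Blood potassium abnormal,24
10,Off label use,24
11,Renal failure,23
12,Weight increased,23
13,Nausea,22
14,Blood pressure increased,21
15,Hyperkalaemia,21
16,Product use issue,21
17,Cardiac failure congestive,19
18,Cerebrovascular accident,19
19,Product dose omission issue,19
20,Abdominal discomfort,18
21,Myocardial infarction,17
22,Pneumonia,17
23,Renal disorder,16
24,Vomiting,16
25,Blood potassium decreased,15
26,Dizziness,15
27,Dysphagia,14
28,Oedema peripheral,14
29,Dyspnoea,13
30,Intentional product misuse,13
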