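rank,pt,count
1,Death,551
2,Blood potassium increased,83
3,Diarrhoea,61
4,Hypokalaemia,56
5,Constipation,53
6,Oedema,37
7,Nausea,34
8,Renal failure,31
9,Off label use,28
10,Product use issue,27
11,Hyperkalaemia,27
12,Blood potassium abnormal,26
13,Drug ineffective,24
14,Cerebrovascular accident,23
15,Cardiac failure congestive,22
16,Oedema peripheral,22
17,Product dose omission issue,22
18,Blood potassium decreased,21
19,Weight increased,21
20,Dizziness,21
21,Myocardial infarction,19
22,Cardiac failure,18
23,Rash,18
24,Abdominal discomfort,17
25,Vomiting,17
26,Peripheral swelling,17
27,Blood pressure increased,17
28,Dyspnoea,17
29,Intentional product misuse,16
30,Renal disorder,15
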