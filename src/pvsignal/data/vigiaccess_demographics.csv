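category,level,count
sex,female,468
sex,male,797
sex,unknown,253
age_group,lt18,1
age_group,a18_44,33
age_group,a45_64,146
age_group,a65_74,197
age_group,ge75,380
age_group,unknown,759
region,africa,7
region,americas,1222
region,asia,169
region,europe,120
region,unknown,0
year,2018,0
year,2019,67
year,2020,115
year,2021,176
year,2022,296
year,2023,303
year,2024,14
year,2025,14
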