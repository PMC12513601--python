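category,level,count
sex,female,380
sex,male,667
sex,unknown,337
age_group,lt18,1
age_group,a18_44,26
age_group,a45_64,99
age_group,a65_74,138
age_group,ge75,324
age_group,unknown,796
region,africa,1
region,americas,1092
region,asia,243
region,europe,48
region,unknown,0
year,2018,6
year,2019,90
year,2020,110
year,2021,160
year,2022,264
year,2023,384
year,2024,388
year,2025,0
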