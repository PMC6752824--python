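rank	label	value	units
1	Lung cancer	1761.0	thousand deaths/yr
2	Colorectal cancer	861.7	thousand deaths/yr
3	Stomach cancer	782.7	thousand deaths/yr
4	Liver cancer	781.6	thousand deaths/yr
5	Breast cancer	626.7	thousand deaths/yr
6	Esophageal cancer	508.6	thousand deaths/yr
7	Head and neck cancer	453.3	thousand deaths/yr
8	Pancreatic cancer	432.2	thousand deaths/yr
9	Prostate cancer	359.0	thousand deaths/yr
10	Cervical cancer	311.4	thousand deaths/yr
11	Leukemia	309.0	thousand deaths/yr
12	Non-Hodgkin lymphoma	248.7	thousand deaths/yr
13	Brain tumor	241.0	thousand deaths/yr
14	Bladder cancer	199.9	thousand deaths/yr
15	Ovarian cancer	184.8	thousand deaths/yr
16	Kidney cancer	175.1	thousand deaths/yr
17	Gallbladder cancer	165.1	thousand deaths/yr
18	Multiple myeloma	106.1	thousand deaths/yr
19	Uterine cancer	89.9	thousand deaths/yr
20	Skin cancer	65.2	thousand deaths/yr
21	Melanoma	60.7	thousand deaths/yr
22	Thyroid cancer	41.1	thousand deaths/yr
23	Hodgkin lymphoma	26.2	thousand deaths/yr
24	Mesothelioma	25.6	thousand deaths/yr
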