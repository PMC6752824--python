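rank	label	value	units
1	Lung cancer	1883.1	thousand deaths/yr
2	Colorectal cancer	896.0	thousand deaths/yr
3	Stomach cancer	865.0	thousand deaths/yr
4	Liver cancer	819.4	thousand deaths/yr
5	Breast cancer	611.6	thousand deaths/yr
6	Pancreatic cancer	441.1	thousand deaths/yr
7	Esophageal cancer	436.0	thousand deaths/yr
8	Prostate cancer	415.9	thousand deaths/yr
9	Head and neck cancer	380.6	thousand deaths/yr
10	Leukemia	347.6	thousand deaths/yr
11	Cervical cancer	259.7	thousand deaths/yr
12	Non-Hodgkin lymphoma	248.6	thousand deaths/yr
13	Brain tumor	247.1	thousand deaths/yr
14	Bladder cancer	196.5	thousand deaths/yr
15	Ovarian cancer	176.0	thousand deaths/yr
16	Gallbladder cancer	174.0	thousand deaths/yr
17	Kidney cancer	138.5	thousand deaths/yr
18	Skin cancer	126.8	thousand deaths/yr
19	Multiple myeloma	107.1	thousand deaths/yr
20	Uterine cancer	85.2	thousand deaths/yr
21	Thyroid cancer	41.2	thousand deaths/yr
22	Hodgkin lymphoma	32.6	thousand deaths/yr
23	Mesothelioma	29.9	thousand deaths/yr
24	Testicular cancer	7.7	thousand deaths/yr
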