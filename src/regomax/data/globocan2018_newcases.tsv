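rank	label	value	units
1	Lung cancer	2093.9	thousand cases/yr
2	Breast cancer	2088.8	thousand cases/yr
3	Colorectal cancer	1801.0	thousand cases/yr
4	Prostate cancer	1276.1	thousand cases/yr
5	Skin cancer	1042.1	thousand cases/yr
6	Stomach cancer	1033.7	thousand cases/yr
7	Head and neck cancer	887.7	thousand cases/yr
8	Liver cancer	841.1	thousand cases/yr
9	Esophageal cancer	572.0	thousand cases/yr
10	Cervical cancer	569.8	thousand cases/yr
11	Thyroid cancer	567.2	thousand cases/yr
12	Bladder cancer	549.4	thousand cases/yr
13	Non-Hodgkin lymphoma	509.6	thousand cases/yr
14	Pancreatic cancer	458.9	thousand cases/yr
15	Leukemia	437.0	thousand cases/yr
16	Kidney cancer	403.3	thousand cases/yr
17	Uterine cancer	382.1	thousand cases/yr
18	Brain tumor	296.9	thousand cases/yr
19	Ovarian cancer	295.4	thousand cases/yr
20	Melanoma	287.7	thousand cases/yr
21	Gallbladder cancer	219.4	thousand cases/yr
22	Multiple myeloma	160.0	thousand cases/yr
23	Hodgkin lymphoma	80.0	thousand cases/yr
24	Testicular cancer	71.1	thousand cases/yr
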