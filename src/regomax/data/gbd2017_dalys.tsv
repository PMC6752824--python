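rank	label	value	units
1	Lung cancer	40900	thousand DALYs/yr
2	Liver cancer	20800	thousand DALYs/yr
3	Stomach cancer	19100	thousand DALYs/yr
4	Colorectal cancer	19000	thousand DALYs/yr
5	Breast cancer	17700	thousand DALYs/yr
6	Leukemia	12000	thousand DALYs/yr
7	Head and neck cancer	10600	thousand DALYs/yr
8	Esophageal cancer	9780	thousand DALYs/yr
9	Pancreatic cancer	9080	thousand DALYs/yr
10	Brain tumor	8740	thousand DALYs/yr
11	Cervical cancer	8060	thousand DALYs/yr
12	Prostate cancer	7060	thousand DALYs/yr
13	Non-Hodgkin lymphoma	7020	thousand DALYs/yr
14	Ovarian cancer	4670	thousand DALYs/yr
15	Bladder cancer	3600	thousand DALYs/yr
16	Gallbladder cancer	3480	thousand DALYs/yr
17	Kidney cancer	3280	thousand DALYs/yr
18	Skin cancer	2980	thousand DALYs/yr
19	Multiple myeloma	2330	thousand DALYs/yr
20	Uterine cancer	2140	thousand DALYs/yr
21	Hodgkin lymphoma	1380	thousand DALYs/yr
22	Thyroid cancer	1130	thousand DALYs/yr
23	Mesothelioma	671	thousand DALYs/yr
24	Testicular cancer	375	thousand DALYs/yr
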