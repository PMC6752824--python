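rank	label	value	units
1	Adrenal tumor		
2	Anal cancer		
3	Appendix cancer		
4	Bladder cancer		
5	Bone tumor		
6	Brain tumor		
7	Breast cancer		
8	Cervical cancer		
9	Cholangiocarcinoma		
10	Colorectal cancer		
11	Esophageal cancer		
12	Gallbladder cancer		
13	Gestational trophoblastic disease		
14	Head and neck cancer		
15	Hodgkin lymphoma		
16	Kidney cancer		
17	Leukemia		
18	Liver cancer		
19	Lung cancer		
20	Melanoma		
21	Mesothelioma		
22	Multiple myeloma		
23	Neuroendocrine tumor		
24	Non-Hodgkin lymphoma		
25	Oral cancer		
26	Ovarian cancer		
27	Pancreatic cancer		
28	Prostate cancer		
29	Skin cancer		
30	Soft-tissue sarcoma		
31	Spinal tumor		
32	Stomach cancer		
33	Testicular cancer		
34	Thyroid cancer		
35	Uterine cancer		
36	Vaginal cancer		
37	Vulvar cancer		
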