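rank	label	value	units	category
1	Lung cancer			cancer
2	Breast cancer			cancer
3	Leukemia			cancer
4	Prostate cancer			cancer
5	Colorectal cancer			cancer
6	Brain tumor			cancer
7	Pancreatic cancer			cancer
8	Melanoma			cancer
9	Stomach cancer			cancer
10	Ovarian cancer			cancer
11	Cervical cancer			cancer
12	Hodgkin lymphoma			cancer
13	Skin cancer			cancer
14	Talc			drug
15	Multiple myeloma			cancer
16	Esophageal cancer			cancer
17	Liver cancer			cancer
18	Non-Hodgkin lymphoma			cancer
19	Bladder cancer			cancer
20	Methotrexate			drug
21	Head and neck cancer			cancer
22	Thalidomide			drug
23	Testicular cancer			cancer
24	Paclitaxel			drug
25	Prednisone			drug
26	Cisplatin			drug
27	Dexamethasone			drug
28	Thyroid cancer			cancer
29	Doxorubicin			drug
30	Bone tumor			cancer
31	Propranolol			drug
32	Interleukin 2			drug
33	Kidney cancer			cancer
34	Mesothelioma			cancer
35	Cyclophosphamide			drug
36	Fluorouracil			drug
37	Oral cancer			cancer
38	Tamoxifen			drug
39	Vincristine			drug
40	Rituximab			drug
41	Bevacizumab			drug
42	HPV vaccines			drug
43	Imatinib			drug
44	Arsenic trioxide			drug
45	Uterine cancer			cancer
46	Dactinomycin			drug
47	Cholangiocarcinoma			cancer
48	Ondansetron			drug
49	Trastuzumab			drug
50	Vinblastine			drug
51	Neuroendocrine tumor			cancer
52	Bleomycin			drug
53	Carboplatin			drug
54	Mercaptopurine			drug
55	Docetaxel			drug
56	Daunorubicin			drug
57	Hyaluronidase			drug
58	Etoposide			drug
59	Bortezomib			drug
60	Irinotecan			drug
61	Soft-tissue sarcoma			cancer
62	Oxaliplatin			drug
63	Melphalan			drug
64	Leuprorelin			drug
65	Raloxifene			drug
66	Hydroxycarbamide			drug
67	Aminolevulinic acid			drug
68	Cytarabine			drug
69	Cetuximab			drug
70	Folinic acid			drug
71	Mitomycin C			drug
72	Anal cancer			cancer
73	Gemcitabine			drug
74	Sorafenib			drug
75	Imiquimod			drug
76	Spinal tumor			cancer
77	Sunitinib			drug
78	Ifosfamide			drug
79	Erlotinib			drug
80	Asparaginase			drug
81	Gefitinib			drug
82	Gestational trophoblastic disease			cancer
83	Anastrozole			drug
84	Epirubicin			drug
85	Lenalidomide			drug
86	Capecitabine			drug
87	Vorinostat			drug
88	Chlormethine			drug
89	Everolimus			drug
90	Alemtuzumab			drug
91	Chlorambucil			drug
92	Filgrastim			drug
93	Goserelin			drug
94	Ipilimumab			drug
95	Temozolomide			drug
96	Peginterferon			drug
97	Mitoxantrone			drug
98	Gallbladder cancer			cancer
99	Vemurafenib			drug
100	Topotecan			drug
101	Fludarabine			drug
102	Pembrolizumab			drug
103	Tioguanine			drug
104	Dacarbazine			drug
105	Azacitidine			drug
106	Vaginal cancer			cancer
107	Carmustine			drug
108	Decitabine			drug
109	Bicalutamide			drug
110	Flutamide			drug
111	Vulvar cancer			cancer
112	Procarbazine			drug
113	Cladribine			drug
114	Tocilizumab			drug
115	Busulfan			drug
116	Denosumab			drug
117	Pemetrexed			drug
118	Lomustine			drug
119	Vinorelbine			drug
120	Nivolumab			drug
121	Dabrafenib			drug
122	Letrozole			drug
123	Fulvestrant			drug
124	Radium-223			drug
125	Olaparib			drug
126	Pazopanib			drug
127	Dasatinib			drug
128	Idarubicin			drug
129	Temsirolimus			drug
130	Exemestane			drug
131	Crizotinib			drug
132	Zoledronic acid			drug
133	Panobinostat			drug
134	Mesna			drug
135	Ibritumomab tiuxetan			drug
136	Trametinib			drug
137	Nilotinib			drug
138	Ixabepilone			drug
139	Megestrol acetate			drug
140	Romiplostim			drug
141	Afatinib			drug
142	ThioTEPA			drug
143	Aprepitant			drug
144	Aflibercept			drug
145	Eribulin			drug
146	Panitumumab			drug
147	Ofatumumab			drug
148	Adrenal tumor			cancer
149	Sipuleucel-T			drug
150	Pamidronic acid			drug
151	Cabozantinib			drug
152	Brentuximab vedotin			drug
153	Gemtuzumab ozogamicin			drug
154	Enzalutamide			drug
155	Pegfilgrastim			drug
156	Romidepsin			drug
157	Rasburicase			drug
158	Bendamustine			drug
159	Interferon alfa-2b			drug
160	Obinutuzumab			drug
161	Denileukin diftitox			drug
162	Ruxolitinib			drug
163	Talimogene laherparepvec			drug
164	Belinostat			drug
165	Eltrombopag			drug
166	Cabazitaxel			drug
167	Lanreotide			drug
168	Palbociclib			drug
169	Pomalidomide			drug
170	Trastuzumab emtansine			drug
171	Vismodegib			drug
172	Appendix cancer			cancer
173	Omacetaxine mepesuccinate			drug
174	Plerixafor			drug
175	Lapatinib			drug
176	Clofarabine			drug
177	Vandetanib			drug
178	Axitinib			drug
179	Ibrutinib			drug
180	Methylnaltrexone			drug
181	Carfilzomib			drug
182	Protein-bound paclitaxel			drug
183	Bosutinib			drug
184	Ceritinib			drug
185	Abiraterone acetate			drug
186	Trabectedin			drug
187	Elotuzumab			drug
188	Nelarabine			drug
189	Palonosetron			drug
190	Cobimetinib			drug
191	Amifostine			drug
192	Atezolizumab			drug
193	Ixazomib			drug
194	Lenvatinib			drug
195	Trifluridine			drug
196	Ponatinib			drug
197	Alectinib			drug
198	Nilutamide			drug
199	Daratumumab			drug
200	Valrubicin			drug
201	Sonidegib			drug
202	Osimertinib			drug
203	Pertuzumab			drug
204	Defibrotide			drug
205	Bexarotene			drug
206	Palifermin			drug
207	Idelalisib			drug
208	Toremifene			drug
209	Apalutamide			drug
210	Regorafenib			drug
211	Venetoclax			drug
212	Dexrazoxane			drug
213	Avelumab			drug
214	Dinutuximab			drug
215	Ramucirumab			drug
216	Blinatumomab			drug
217	Rolapitant			drug
218	Niraparib			drug
219	Pralatrexate			drug
220	Acalabrutinib			drug
221	Brigatinib			drug
222	Necitumumab			drug
223	Midostaurin			drug
224	Rucaparib			drug
225	Inotuzumab ozogamicin			drug
226	Pegaspargase			drug
227	Durvalumab			drug
228	Siltuximab			drug
229	Ribociclib			drug
230	Degarelix			drug
231	Neratinib			drug
232	Abemaciclib			drug
233	Olaratumab			drug
234	Copanlisib			drug
235	Netupitant/palonosetron			drug
236	Tipiracil			drug
237	Uridine triacetate			drug
238	Axicabtagene ciloleucel			drug
239	Glucarpidase			drug
240	Tisagenlecleucel			drug
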