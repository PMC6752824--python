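rank	label	value	units
1	Abemaciclib		
2	Abiraterone acetate		
3	Acalabrutinib		
4	Afatinib		
5	Aflibercept		
6	Alectinib		
7	Alemtuzumab		
8	Amifostine		
9	Aminolevulinic acid		
10	Anastrozole		
11	Apalutamide		
12	Aprepitant		
13	Arsenic trioxide		
14	Asparaginase		
15	Atezolizumab		
16	Avelumab		
17	Axicabtagene ciloleucel		
18	Axitinib		
19	Azacitidine		
20	Belinostat		
21	Bendamustine		
22	Bevacizumab		
23	Bexarotene		
24	Bicalutamide		
25	Bleomycin		
26	Blinatumomab		
27	Bortezomib		
28	Bosutinib		
29	Brentuximab vedotin		
30	Brigatinib		
31	Busulfan		
32	Cabazitaxel		
33	Cabozantinib		
34	Capecitabine		
35	Carboplatin		
36	Carfilzomib		
37	Carmustine		
38	Ceritinib		
39	Cetuximab		
40	Chlorambucil		
41	Chlormethine		
42	Cisplatin		
43	Cladribine		
44	Clofarabine		
45	Cobimetinib		
46	Copanlisib		
47	Crizotinib		
48	Cyclophosphamide		
49	Cytarabine		
50	Dabrafenib		
51	Dacarbazine		
52	Dactinomycin		
53	Daratumumab		
54	Dasatinib		
55	Daunorubicin		
56	Decitabine		
57	Defibrotide		
58	Degarelix		
59	Denileukin diftitox		
60	Denosumab		
61	Dexamethasone		
62	Dexrazoxane		
63	Dinutuximab		
64	Docetaxel		
65	Doxorubicin		
66	Durvalumab		
67	Elotuzumab		
68	Eltrombopag		
69	Enzalutamide		
70	Epirubicin		
71	Eribulin		
72	Erlotinib		
73	Etoposide		
74	Everolimus		
75	Exemestane		
76	Filgrastim		
77	Fludarabine		
78	Fluorouracil		
79	Flutamide		
80	Folinic acid		
81	Fulvestrant		
82	Gefitinib		
83	Gemcitabine		
84	Gemtuzumab ozogamicin		
85	Glucarpidase		
86	Goserelin		
87	HPV vaccines		
88	Hyaluronidase		
89	Hydroxycarbamide		
90	Ibritumomab tiuxetan		
91	Ibrutinib		
92	Idarubicin		
93	Idelalisib		
94	Ifosfamide		
95	Imatinib		
96	Imiquimod		
97	Inotuzumab ozogamicin		
98	Interferon alfa-2b		
99	Interleukin 2		
100	Ipilimumab		
101	Irinotecan		
102	Ixabepilone		
103	Ixazomib		
104	Lanreotide		
105	Lapatinib		
106	Lenalidomide		
107	Lenvatinib		
108	Letrozole		
109	Leuprorelin		
110	Lomustine		
111	Megestrol acetate		
112	Melphalan		
113	Mercaptopurine		
114	Mesna		
115	Methotrexate		
116	Methylnaltrexone		
117	Midostaurin		
118	Mitomycin C		
119	Mitoxantrone		
120	Necitumumab		
121	Nelarabine		
122	Neratinib		
123	Netupitant/palonosetron		
124	Nilotinib		
125	Nilutamide		
126	Niraparib		
127	Nivolumab		
128	Obinutuzumab		
129	Ofatumumab		
130	Olaparib		
131	Olaratumab		
132	Omacetaxine mepesuccinate		
133	Ondansetron		
134	Osimertinib		
135	Oxaliplatin		
136	Paclitaxel		
137	Palbociclib		
138	Palifermin		
139	Palonosetron		
140	Pamidronic acid		
141	Panitumumab		
142	Panobinostat		
143	Pazopanib		
144	Pegaspargase		
145	Pegfilgrastim		
146	Peginterferon		
147	Pembrolizumab		
148	Pemetrexed		
149	Pertuzumab		
150	Plerixafor		
151	Pomalidomide		
152	Ponatinib		
153	Pralatrexate		
154	Prednisone		
155	Procarbazine		
156	Propranolol		
157	Protein-bound paclitaxel		
158	Radium-223		
159	Raloxifene		
160	Ramucirumab		
161	Rasburicase		
162	Regorafenib		
163	Ribociclib		
164	Rituximab		
165	Rolapitant		
166	Romidepsin		
167	Romiplostim		
168	Rucaparib		
169	Ruxolitinib		
170	Siltuximab		
171	Sipuleucel-T		
172	Sonidegib		
173	Sorafenib		
174	Sunitinib		
175	Talc		
176	Talimogene laherparepvec		
177	Tamoxifen		
178	Temozolomide		
179	Temsirolimus		
180	Thalidomide		
181	ThioTEPA		
182	Tioguanine		
183	Tipiracil		
184	Tisagenlecleucel		
185	Tocilizumab		
186	Topotecan		
187	Toremifene		
188	Trabectedin		
189	Trametinib		
190	Trastuzumab		
191	Trastuzumab emtansine		
192	Trifluridine		
193	Uridine triacetate		
194	Valrubicin		
195	Vandetanib		
196	Vemurafenib		
197	Venetoclax		
198	Vinblastine		
199	Vincristine		
200	Vinorelbine		
201	Vismodegib		
202	Vorinostat		
203	Zoledronic acid		
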