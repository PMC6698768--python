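# canonical feature manifest: index<TAB>name<TAB>family
1	hist_mean	histogram
2	hist_variance	histogram
3	hist_skewness	histogram
4	hist_kurtosis	histogram
5	hist_median	histogram
6	hist_min	histogram
7	hist_max	histogram
8	hist_range	histogram
9	hist_p10	histogram
10	hist_p90	histogram
11	hist_mad	histogram
12	hist_energy	histogram
13	hist_entropy	histogram
14	glcm_2d_0_energy	glcm_2d
15	glcm_2d_0_contrast	glcm_2d
16	glcm_2d_0_correlation	glcm_2d
17	glcm_2d_0_variance	glcm_2d
18	glcm_2d_0_idm	glcm_2d
19	glcm_2d_0_sum_average	glcm_2d
20	glcm_2d_0_sum_variance	glcm_2d
21	glcm_2d_0_sum_entropy	glcm_2d
22	glcm_2d_0_entropy	glcm_2d
23	glcm_2d_0_difference_variance	glcm_2d
24	glcm_2d_0_difference_entropy	glcm_2d
25	glcm_2d_0_imc1	glcm_2d
26	glcm_2d_0_imc2	glcm_2d
27	glcm_2d_0_autocorrelation	glcm_2d
28	glcm_2d_0_max_probability	glcm_2d
29	glcm_2d_45_energy	glcm_2d
30	glcm_2d_45_contrast	glcm_2d
31	glcm_2d_45_correlation	glcm_2d
32	glcm_2d_45_variance	glcm_2d
33	glcm_2d_45_idm	glcm_2d
34	glcm_2d_45_sum_average	glcm_2d
35	glcm_2d_45_sum_variance	glcm_2d
36	glcm_2d_45_sum_entropy	glcm_2d
37	glcm_2d_45_entropy	glcm_2d
38	glcm_2d_45_difference_variance	glcm_2d
39	glcm_2d_45_difference_entropy	glcm_2d
40	glcm_2d_45_imc1	glcm_2d
41	glcm_2d_45_imc2	glcm_2d
42	glcm_2d_45_autocorrelation	glcm_2d
43	glcm_2d_45_max_probability	glcm_2d
44	glcm_2d_90_energy	glcm_2d
45	glcm_2d_90_contrast	glcm_2d
46	glcm_2d_90_correlation	glcm_2d
47	glcm_2d_90_variance	glcm_2d
48	glcm_2d_90_idm	glcm_2d
49	glcm_2d_90_sum_average	glcm_2d
50	glcm_2d_90_sum_variance	glcm_2d
51	glcm_2d_90_sum_entropy	glcm_2d
52	glcm_2d_90_entropy	glcm_2d
53	glcm_2d_90_difference_variance	glcm_2d
54	glcm_2d_90_difference_entropy	glcm_2d
55	glcm_2d_90_imc1	glcm_2d
56	glcm_2d_90_imc2	glcm_2d
57	glcm_2d_90_autocorrelation	glcm_2d
58	glcm_2d_90_max_probability	glcm_2d
59	glcm_2d_135_energy	glcm_2d
60	glcm_2d_135_contrast	glcm_2d
61	glcm_2d_135_correlation	glcm_2d
62	glcm_2d_135_variance	glcm_2d
63	glcm_2d_135_idm	glcm_2d
64	glcm_2d_135_sum_average	glcm_2d
65	glcm_2d_135_sum_variance	glcm_2d
66	glcm_2d_135_sum_entropy	glcm_2d
67	glcm_2d_135_entropy	glcm_2d
68	glcm_2d_135_difference_variance	glcm_2d
69	glcm_2d_135_difference_entropy	glcm_2d
70	glcm_2d_135_imc1	glcm_2d
71	glcm_2d_135_imc2	glcm_2d
72	glcm_2d_135_autocorrelation	glcm_2d
73	glcm_2d_135_max_probability	glcm_2d
74	gldm_2d_0_contrast	gldm_2d
75	gldm_2d_0_asm	gldm_2d
76	gldm_2d_0_entropy	gldm_2d
77	gldm_2d_0_mean	gldm_2d
78	gldm_2d_0_idm	gldm_2d
79	gldm_2d_45_contrast	gldm_2d
80	gldm_2d_45_asm	gldm_2d
81	gldm_2d_45_entropy	gldm_2d
82	gldm_2d_45_mean	gldm_2d
83	gldm_2d_45_idm	gldm_2d
84	gldm_2d_90_contrast	gldm_2d
85	gldm_2d_90_asm	gldm_2d
86	gldm_2d_90_entropy	gldm_2d
87	gldm_2d_90_mean	gldm_2d
88	gldm_2d_90_idm	gldm_2d
89	gldm_2d_135_contrast	gldm_2d
90	gldm_2d_135_asm	gldm_2d
91	gldm_2d_135_entropy	gldm_2d
92	gldm_2d_135_mean	gldm_2d
93	gldm_2d_135_idm	gldm_2d
94	glcm_3d_mean_energy	glcm_3d
95	glcm_3d_mean_contrast	glcm_3d
96	glcm_3d_mean_correlation	glcm_3d
97	glcm_3d_mean_variance	glcm_3d
98	glcm_3d_mean_idm	glcm_3d
99	glcm_3d_mean_sum_average	glcm_3d
100	glcm_3d_mean_sum_variance	glcm_3d
101	glcm_3d_mean_sum_entropy	glcm_3d
102	glcm_3d_mean_entropy	glcm_3d
103	glcm_3d_mean_difference_variance	glcm_3d
104	glcm_3d_mean_difference_entropy	glcm_3d
105	glcm_3d_mean_imc1	glcm_3d
106	glcm_3d_mean_imc2	glcm_3d
107	glcm_3d_mean_autocorrelation	glcm_3d
108	glcm_3d_mean_max_probability	glcm_3d
109	glcm_3d_range_energy	glcm_3d
110	glcm_3d_range_contrast	glcm_3d
111	glcm_3d_range_correlation	glcm_3d
112	glcm_3d_range_variance	glcm_3d
113	glcm_3d_range_idm	glcm_3d
114	glcm_3d_range_sum_average	glcm_3d
115	glcm_3d_range_sum_variance	glcm_3d
116	glcm_3d_range_sum_entropy	glcm_3d
117	glcm_3d_range_entropy	glcm_3d
118	glcm_3d_range_difference_variance	glcm_3d
119	glcm_3d_range_difference_entropy	glcm_3d
120	glcm_3d_range_imc1	glcm_3d
121	glcm_3d_range_imc2	glcm_3d
122	glcm_3d_range_autocorrelation	glcm_3d
123	glcm_3d_range_max_probability	glcm_3d
124	glcm_3d_min_energy	glcm_3d
125	glcm_3d_min_contrast	glcm_3d
126	glcm_3d_min_correlation	glcm_3d
127	glcm_3d_min_variance	glcm_3d
128	glcm_3d_min_idm	glcm_3d
129	glcm_3d_min_sum_average	glcm_3d
130	glcm_3d_min_sum_variance	glcm_3d
131	glcm_3d_min_sum_entropy	glcm_3d
132	glcm_3d_min_entropy	glcm_3d
133	glcm_3d_min_difference_variance	glcm_3d
134	glcm_3d_min_difference_entropy	glcm_3d
135	glcm_3d_min_imc1	glcm_3d
136	glcm_3d_min_imc2	glcm_3d
137	glcm_3d_min_autocorrelation	glcm_3d
138	glcm_3d_min_max_probability	glcm_3d
139	glcm_3d_max_energy	glcm_3d
140	glcm_3d_max_contrast	glcm_3d
141	glcm_3d_max_correlation	glcm_3d
142	glcm_3d_max_variance	glcm_3d
143	glcm_3d_max_idm	glcm_3d
144	glcm_3d_max_sum_average	glcm_3d
145	glcm_3d_max_sum_variance	glcm_3d
146	glcm_3d_max_sum_entropy	glcm_3d
147	glcm_3d_max_entropy	glcm_3d
148	glcm_3d_max_difference_variance	glcm_3d
149	glcm_3d_max_difference_entropy	glcm_3d
150	glcm_3d_max_imc1	glcm_3d
151	glcm_3d_max_imc2	glcm_3d
152	glcm_3d_max_autocorrelation	glcm_3d
153	glcm_3d_max_max_probability	glcm_3d
154	gldm_3d_mean_contrast	gldm_3d
155	gldm_3d_mean_asm	gldm_3d
156	gldm_3d_mean_entropy	gldm_3d
157	gldm_3d_mean_mean	gldm_3d
158	gldm_3d_mean_idm	gldm_3d
159	gldm_3d_range_contrast	gldm_3d
160	gldm_3d_range_asm	gldm_3d
161	gldm_3d_range_entropy	gldm_3d
162	gldm_3d_range_mean	gldm_3d
163	gldm_3d_range_idm	gldm_3d
164	gldm_3d_min_contrast	gldm_3d
165	gldm_3d_min_asm	gldm_3d
166	gldm_3d_min_entropy	gldm_3d
167	gldm_3d_min_mean	gldm_3d
168	gldm_3d_min_idm	gldm_3d
169	gldm_3d_max_contrast	gldm_3d
170	gldm_3d_max_asm	gldm_3d
171	gldm_3d_max_entropy	gldm_3d
172	gldm_3d_max_mean	gldm_3d
173	gldm_3d_max_idm	gldm_3d
174	glrlm_2d_mean_sre	glrlm_2d
175	glrlm_2d_mean_lre	glrlm_2d
176	glrlm_2d_mean_gln	glrlm_2d
177	glrlm_2d_mean_rln	glrlm_2d
178	glrlm_2d_mean_rp	glrlm_2d
179	glrlm_2d_mean_lgre	glrlm_2d
180	glrlm_2d_mean_hgre	glrlm_2d
181	glrlm_2d_mean_srlge	glrlm_2d
182	glrlm_2d_mean_srhge	glrlm_2d
183	glrlm_2d_mean_lrlge	glrlm_2d
184	glrlm_2d_mean_lrhge	glrlm_2d
185	glrlm_2d_min_sre	glrlm_2d
186	glrlm_2d_min_lre	glrlm_2d
187	glrlm_2d_min_gln	glrlm_2d
188	glrlm_2d_min_rln	glrlm_2d
189	glrlm_2d_min_rp	glrlm_2d
190	glrlm_2d_min_lgre	glrlm_2d
191	glrlm_2d_min_hgre	glrlm_2d
192	glrlm_2d_min_srlge	glrlm_2d
193	glrlm_2d_min_srhge	glrlm_2d
194	glrlm_2d_min_lrlge	glrlm_2d
195	glrlm_2d_min_lrhge	glrlm_2d
196	glrlm_2d_max_sre	glrlm_2d
197	glrlm_2d_max_lre	glrlm_2d
198	glrlm_2d_max_gln	glrlm_2d
199	glrlm_2d_max_rln	glrlm_2d
200	glrlm_2d_max_rp	glrlm_2d
201	glrlm_2d_max_lgre	glrlm_2d
202	glrlm_2d_max_hgre	glrlm_2d
203	glrlm_2d_max_srlge	glrlm_2d
204	glrlm_2d_max_srhge	glrlm_2d
205	glrlm_2d_max_lrlge	glrlm_2d
206	glrlm_2d_max_lrhge	glrlm_2d
207	glrlm_3d_mean_sre	glrlm_3d
208	glrlm_3d_mean_lre	glrlm_3d
209	glrlm_3d_mean_gln	glrlm_3d
210	glrlm_3d_mean_rln	glrlm_3d
211	glrlm_3d_mean_rp	glrlm_3d
212	glrlm_3d_mean_lgre	glrlm_3d
213	glrlm_3d_mean_hgre	glrlm_3d
214	glrlm_3d_mean_srlge	glrlm_3d
215	glrlm_3d_mean_srhge	glrlm_3d
216	glrlm_3d_mean_lrlge	glrlm_3d
217	glrlm_3d_mean_lrhge	glrlm_3d
218	fft_mag_mean	fft
219	fft_mag_std	fft
220	fft_mag_skewness	fft
221	fft_mag_kurtosis	fft
222	fft_mag_energy	fft
223	fft_mag_entropy	fft
224	fft_mag_max	fft
225	fft_mag_radial_centroid	fft
226	fft_mag_radial_spread	fft
227	fft_phase_mean	fft
228	fft_phase_std	fft
229	fft_phase_skewness	fft
230	fft_phase_kurtosis	fft
231	fft_phase_energy	fft
232	fft_phase_entropy	fft
233	fft_phase_max	fft
234	fft_phase_radial_centroid	fft
235	fft_phase_radial_spread	fft
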