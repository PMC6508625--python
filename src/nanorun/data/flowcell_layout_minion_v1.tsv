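# minion-512 layout, version 1: eight 64-channel blocks of 16 rows x 4 cols, left to right
channel	row	col
1	0	0
2	0	1
3	0	2
4	0	3
5	1	0
6	1	1
7	1	2
8	1	3
9	2	0
10	2	1
11	2	2
12	2	3
13	3	0
14	3	1
15	3	2
16	3	3
17	4	0
18	4	1
19	4	2
20	4	3
21	5	0
22	5	1
23	5	2
24	5	3
25	6	0
26	6	1
27	6	2
28	6	3
29	7	0
30	7	1
31	7	2
32	7	3
33	8	0
34	8	1
35	8	2
36	8	3
37	9	0
38	9	1
39	9	2
40	9	3
41	10	0
42	10	1
43	10	2
44	10	3
45	11	0
46	11	1
47	11	2
48	11	3
49	12	0
50	12	1
51	12	2
52	12	3
53	13	0
54	13	1
55	13	2
56	13	3
57	14	0
58	14	1
59	14	2
60	14	3
61	15	0
62	15	1
63	15	2
64	15	3
65	0	4
66	0	5
67	0	6
68	0	7
69	1	4
70	1	5
71	1	6
72	1	7
73	2	4
74	2	5
75	2	6
76	2	7
77	3	4
78	3	5
79	3	6
80	3	7
81	4	4
82	4	5
83	4	6
84	4	7
85	5	4
86	5	5
87	5	6
88	5	7
89	6	4
90	6	5
91	6	6
92	6	7
93	7	4
94	7	5
95	7	6
96	7	7
97	8	4
98	8	5
99	8	6
100	8	7
101	9	4
102	9	5
103	9	6
104	9	7
105	10	4
106	10	5
107	10	6
108	10	7
109	11	4
110	11	5
111	11	6
112	11	7
113	12	4
114	12	5
115	12	6
116	12	7
117	13	4
118	13	5
119	13	6
120	13	7
121	14	4
122	14	5
123	14	6
124	14	7
125	15	4
126	15	5
127	15	6
128	15	7
129	0	8
130	0	9
131	0	10
132	0	11
133	1	8
134	1	9
135	1	10
136	1	11
137	2	8
138	2	9
139	2	10
140	2	11
141	3	8
142	3	9
143	3	10
144	3	11
145	4	8
146	4	9
147	4	10
148	4	11
149	5	8
150	5	9
151	5	10
152	5	11
153	6	8
154	6	9
155	6	10
156	6	11
157	7	8
158	7	9
159	7	10
160	7	11
161	8	8
162	8	9
163	8	10
164	8	11
165	9	8
166	9	9
167	9	10
168	9	11
169	10	8
170	10	9
171	10	10
172	10	11
173	11	8
174	11	9
175	11	10
176	11	11
177	12	8
178	12	9
179	12	10
180	12	11
181	13	8
182	13	9
183	13	10
184	13	11
185	14	8
186	14	9
187	14	10
188	14	11
189	15	8
190	15	9
191	15	10
192	15	11
193	0	12
194	0	13
195	0	14
196	0	15
197	1	12
198	1	13
199	1	14
200	1	15
201	2	12
202	2	13
203	2	14
204	2	15
205	3	12
206	3	13
207	3	14
208	3	15
209	4	12
210	4	13
211	4	14
212	4	15
213	5	12
214	5	13
215	5	14
216	5	15
217	6	12
218	6	13
219	6	14
220	6	15
221	7	12
222	7	13
223	7	14
224	7	15
225	8	12
226	8	13
227	8	14
228	8	15
229	9	12
230	9	13
231	9	14
232	9	15
233	10	12
234	10	13
235	10	14
236	10	15
237	11	12
238	11	13
239	11	14
240	11	15
241	12	12
242	12	13
243	12	14
244	12	15
245	13	12
246	13	13
247	13	14
248	13	15
249	14	12
250	14	13
251	14	14
252	14	15
253	15	12
254	15	13
255	15	14
256	15	15
257	0	16
258	0	17
259	0	18
260	0	19
261	1	16
262	1	17
263	1	18
264	1	19
265	2	16
266	2	17
267	2	18
268	2	19
269	3	16
270	3	17
271	3	18
272	3	19
273	4	16
274	4	17
275	4	18
276	4	19
277	5	16
278	5	17
279	5	18
280	5	19
281	6	16
282	6	17
283	6	18
284	6	19
285	7	16
286	7	17
287	7	18
288	7	19
289	8	16
290	8	17
291	8	18
292	8	19
293	9	16
294	9	17
295	9	18
296	9	19
297	10	16
298	10	17
299	10	18
300	10	19
301	11	16
302	11	17
303	11	18
304	11	19
305	12	16
306	12	17
307	12	18
308	12	19
309	13	16
310	13	17
311	13	18
312	13	19
313	14	16
314	14	17
315	14	18
316	14	19
317	15	16
318	15	17
319	15	18
320	15	19
321	0	20
322	0	21
323	0	22
324	0	23
325	1	20
326	1	21
327	1	22
328	1	23
329	2	20
330	2	21
331	2	22
332	2	23
333	3	20
334	3	21
335	3	22
336	3	23
337	4	20
338	4	21
339	4	22
340	4	23
341	5	20
342	5	21
343	5	22
344	5	23
345	6	20
346	6	21
347	6	22
348	6	23
349	7	20
350	7	21
351	7	22
352	7	23
353	8	20
354	8	21
355	8	22
356	8	23
357	9	20
358	9	21
359	9	22
360	9	23
361	10	20
362	10	21
363	10	22
364	10	23
365	11	20
366	11	21
367	11	22
368	11	23
369	12	20
370	12	21
371	12	22
372	12	23
373	13	20
374	13	21
375	13	22
376	13	23
377	14	20
378	14	21
379	14	22
380	14	23
381	15	20
382	15	21
383	15	22
384	15	23
385	0	24
386	0	25
387	0	26
388	0	27
389	1	24
390	1	25
391	1	26
392	1	27
393	2	24
394	2	25
395	2	26
396	2	27
397	3	24
398	3	25
399	3	26
400	3	27
401	4	24
402	4	25
403	4	26
404	4	27
405	5	24
406	5	25
407	5	26
408	5	27
409	6	24
410	6	25
411	6	26
412	6	27
413	7	24
414	7	25
415	7	26
416	7	27
417	8	24
418	8	25
419	8	26
420	8	27
421	9	24
422	9	25
423	9	26
424	9	27
425	10	24
426	10	25
427	10	26
428	10	27
429	11	24
430	11	25
431	11	26
432	11	27
433	12	24
434	12	25
435	12	26
436	12	27
437	13	24
438	13	25
439	13	26
440	13	27
441	14	24
442	14	25
443	14	26
444	14	27
445	15	24
446	15	25
447	15	26
448	15	27
449	0	28
450	0	29
451	0	30
452	0	31
453	1	28
454	1	29
455	1	30
456	1	31
457	2	28
458	2	29
459	2	30
460	2	31
461	3	28
462	3	29
463	3	30
464	3	31
465	4	28
466	4	29
467	4	30
468	4	31
469	5	28
470	5	29
471	5	30
472	5	31
473	6	28
474	6	29
475	6	30
476	6	31
477	7	28
478	7	29
479	7	30
480	7	31
481	8	28
482	8	29
483	8	30
484	8	31
485	9	28
486	9	29
487	9	30
488	9	31
489	10	28
490	10	29
491	10	30
492	10	31
493	11	28
494	11	29
495	11	30
496	11	31
497	12	28
498	12	29
499	12	30
500	12	31
501	13	28
502	13	29
503	13	30
504	13	31
505	14	28
506	14	29
507	14	30
508	14	31
509	15	28
510	15	29
511	15	30
512	15	31
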