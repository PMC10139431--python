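snp	chr	pos	effect_allele	other_allele	beta	se	pval	eaf	trait
rs1018326	2	182007800	C	T	0.1519		3.78e-9		Celiac disease
rs11221335	11	128385906	C	T	0.2175		4.16e-11		Celiac disease
rs13003464	2	61186829	G	A	0.1415		4.92e-8		Celiac disease
rs13098911	3	46235201	T	C	0.2784		2.53e-11		Celiac disease
rs13151961	4	123115502	G	A	-0.3239		6.31e-18		Celiac disease
rs1738074	6	159465977	C	T	-0.1424		3.14e-8		Celiac disease
rs17810546	3	159665050	G	A	0.3235		4.56e-18		Celiac disease
rs2327832	6	138006504	G	A	0.2319		1.41e-14		Celiac disease
rs2816316	1	192536813	A	C	0.2544		1.45e-12		Celiac disease
rs653178	12	112007756	T	C	-0.1923		6.03e-14		Celiac disease
rs917997	2	103070568	C	T	-0.2319		5.97e-15		Celiac disease
rs1018326	2	182007800	C	T	5.00e-4		9.96e-1	0.4994	Diffuse large B-cell lymphoma
rs11221335	11	128385906	C	T	-3.88e-2		7.38e-1	0.2342	Diffuse large B-cell lymphoma
rs13003464	2	61186829	G	A	-3.34e-2		7.42e-1	0.3696	Diffuse large B-cell lymphoma
rs13098911	3	46235201	T	C	9.46e-2		4.98e-1	0.1461	Diffuse large B-cell lymphoma
rs13151961	4	123115502	G	A	1.99e-1		1.95e-1	0.1145	Diffuse large B-cell lymphoma
rs1738074	6	159465977	C	T	-6.17e-2		5.36e-1	0.5824	Diffuse large B-cell lymphoma
rs17810546	3	159665050	G	A	-1.61e-1		3.25e-1	0.09909	Diffuse large B-cell lymphoma
rs2327832 (rs6920220)	6	138006504	G	A	-1.02e-1		4.11e-1	0.1888	Diffuse large B-cell lymphoma
rs2816316	1	192536813	A	C	2.00e-1		1.47e-1	0.8538	Diffuse large B-cell lymphoma
rs653178	12	112007756	T	C	1.54e-1		1.22e-1	0.584	Diffuse large B-cell lymphoma
rs917997	2	103070568	C	T	3.00e-2		8.09e-1	0.8084	Diffuse large B-cell lymphoma
rs1018326	2	182007800	C	T	-3.07e-2		6.22e-1	0.4994	Follicular lymphoma
rs11221335	11	128385906	C	T	-1.26e-2		8.64e-1	0.2342	Follicular lymphoma
rs13003464	2	61186829	G	A	7.02e-2		2.74e-1	0.3696	Follicular lymphoma
rs13098911	3	46235201	T	C	-7.04e-2		4.25e-1	0.1461	Follicular lymphoma
rs13151961	4	123115502	G	A	-1.03e-1		2.93e-1	0.1145	Follicular lymphoma
rs1738074	6	159465977	C	T	-1.77e-2		7.79e-1	0.5824	Follicular lymphoma
rs17810546	3	159665050	G	A	-1.01e-1		3.30e-1	0.09909	Follicular lymphoma
rs2327832 (rs6920220)	6	138006504	G	A	-7.97e-2		3.13e-1	0.1888	Follicular lymphoma
rs2816316	1	192536813	A	C	-5.29e-2		5.46e-1	0.8538	Follicular lymphoma
rs653178	12	112007756	T	C	-6.25e-2		3.21e-1	0.584	Follicular lymphoma
rs917997	2	103070568	C	T	5.11e-2		5.15e-1	0.8084	Follicular lymphoma
rs1018326	2	182007800	C	T	8.30e-3		9.11e-1	0.4994	Hodgkin lymphoma
rs11221335	11	128385906	C	T	7.96e-2		3.61e-1	0.2342	Hodgkin lymphoma
rs13003464	2	61186829	G	A	1.83e-1		1.70e-2	0.3696	Hodgkin lymphoma
rs13098911	3	46235201	T	C	-1.14e-1		2.81e-1	0.1461	Hodgkin lymphoma
rs13151961	4	123115502	G	A	-7.82e-2		5.01e-1	0.1145	Hodgkin lymphoma
rs1738074	6	159465977	C	T	2.11e-2		7.79e-1	0.5824	Hodgkin lymphoma
rs17810546	3	159665050	G	A	4.27e-2		7.30e-1	0.09909	Hodgkin lymphoma
rs2327832 (rs6920220)	6	138006504	G	A	-2.15e-2		8.19e-1	0.1888	Hodgkin lymphoma
rs2816316	1	192536813	A	C	-7.50e-3		9.43e-1	0.8538	Hodgkin lymphoma
rs653178	12	112007756	T	C	4.56e-2		5.44e-1	0.584	Hodgkin lymphoma
rs917997	2	103070568	C	T	-6.82e-2		4.68e-1	0.8084	Hodgkin lymphoma
rs1018326	2	182007800	C	T	-3.43e-2		3.92e-1	0.4994	Non-follicular lymphoma
rs11221335	11	128385906	C	T	4.88e-2		3.00e-1	0.2342	Non-follicular lymphoma
rs13003464	2	61186829	G	A	5.75e-2		1.64e-1	0.3696	Non-follicular lymphoma
rs13098911	3	46235201	T	C	-2.86e-2		6.15e-1	0.1461	Non-follicular lymphoma
rs13151961	4	123115502	G	A	-1.06e-2		8.66e-1	0.1145	Non-follicular lymphoma
rs1738074	6	159465977	C	T	-1.90e-2		6.40e-1	0.5824	Non-follicular lymphoma
rs17810546	3	159665050	G	A	6.50e-3		9.22e-1	0.09909	Non-follicular lymphoma
rs2327832 (rs6920220)	6	138006504	G	A	-7.19e-2		1.57e-1	0.1888	Non-follicular lymphoma
rs2816316	1	192536813	A	C	6.84e-2		2.25e-1	0.8538	Non-follicular lymphoma
rs653178	12	112007756	T	C	9.04e-2		2.58e-1	0.584	Non-follicular lymphoma
rs917997	2	103070568	C	T	5.16e-2		3.09e-1	0.8084	Non-follicular lymphoma
rs1018326	2	182007800	C	T	2.00e-3		9.74e-1	0.4994	Other and unspecified types of non-Hodgkin lymphoma
rs11221335	11	128385906	C	T	7.59e-2		2.97e-1	0.2342	Other and unspecified types of non-Hodgkin lymphoma
rs13003464	2	61186829	G	A	2.51e-2		6.93e-1	0.3696	Other and unspecified types of non-Hodgkin lymphoma
rs13098911	3	46235201	T	C	-3.00e-2		7.33e-1	0.1461	Other and unspecified types of non-Hodgkin lymphoma
rs13151961	4	123115502	G	A	2.40e-3		9.80e-1	0.1145	Other and unspecified types of non-Hodgkin lymphoma
rs1738074	6	159465977	C	T	-1.11e-2		8.60e-1	0.5824	Other and unspecified types of non-Hodgkin lymphoma
rs17810546	3	159665050	G	A	-7.88e-2		4.43e-1	0.09909	Other and unspecified types of non-Hodgkin lymphoma
rs2327832 (rs6920220)	6	138006504	G	A	-6.06e-2		4.39e-1	0.1888	Other and unspecified types of non-Hodgkin lymphoma
rs2816316	1	192536813	A	C	2.51e-2		7.72e-1	0.8538	Other and unspecified types of non-Hodgkin lymphoma
rs653178	12	112007756	T	C	5.10e-2		4.14e-1	0.584	Other and unspecified types of non-Hodgkin lymphoma
rs917997	2	103070568	C	T	-2.91e-2		7.09e-1	0.8084	Other and unspecified types of non-Hodgkin lymphoma
rs1018326	2	182007800	C	T	1.95e-1		9.25e-2	0.4994	Mature T/NK-cell lymphomas
rs11221335	11	128385906	C	T	-2.89e-2		8.32e-1	0.2342	Mature T/NK-cell lymphomas
rs13003464	2	61186829	G	A	1.54e-1		1.97e-1	0.3696	Mature T/NK-cell lymphomas
rs13098911	3	46235201	T	C	-1.15e-1		4.86e-1	0.1461	Mature T/NK-cell lymphomas
rs13151961	4	123115502	G	A	-5.31e-2		7.69e-1	0.1145	Mature T/NK-cell lymphomas
rs1738074	6	159465977	C	T	-2.67e-1		2.33e-2	0.5824	Mature T/NK-cell lymphomas
rs17810546	3	159665050	G	A	6.38e-2		7.40e-1	0.09909	Mature T/NK-cell lymphomas
rs2327832 (rs6920220)	6	138006504	G	A	1.53e-1		2.97e-1	0.1888	Mature T/NK-cell lymphomas
rs2816316	1	192536813	A	C	2.82e-1		8.31e-2	0.8538	Mature T/NK-cell lymphomas
rs653178	12	112007756	T	C	-1.76e-1		1.33e-1	0.584	Mature T/NK-cell lymphomas
rs917997	2	103070568	C	T	-1.28e-1		3.82e-1	0.8084	Mature T/NK-cell lymphomas
rs1018326	2	182007800	C	T	-5.26e-5		7.51e-1	0.42235	Lymphomas
rs11221335	11	128385906	C	T	2.47e-4		2.17e-1	0.21227	Lymphomas
rs13003464	2	61186829	G	A	3.00e-4		7.58e-2	0.37623	Lymphomas
rs13098911	3	46235201	T	C	-1.79e-4		5.64e-1	0.07501	Lymphomas
rs13151961	4	123115502	G	A	8.67e-5		6.87e-1	0.17478	Lymphomas
rs1738074	6	159465977	C	T	9.34e-5		5.70e-1	0.56446	Lymphomas
rs17810546	3	159665050	G	A	1.99e-4		4.22e-1	0.12335	Lymphomas
rs2327832	6	137973068	G	A	6.79e-5		7.30e-1	0.22264	Lymphomas
rs2816316	1	192536813	A	C	-2.90e-6		9.89e-1	0.81835	Lymphomas
rs653178	12	112007756	T	C	1.95e-4		2.34e-1	0.51724	Lymphomas
rs917997	2	103070568	C	T	-1.54e-4		4.33e-1	0.77549	Lymphomas
rs1018326	2	182007800	C	T	-7.65e-5		1.49e-1	0.42222	Small intestine/small bowel cancer
rs11221335	11	128385906	C	T	2.71e-5		6.72e-1	0.21196	Small intestine/small bowel cancer
rs13003464	2	61186829	G	A	-8.21e-5		1.29e-1	0.37657	Small intestine/small bowel cancer
rs13098911	3	46235201	T	C	1.15e-4		2.47e-1	0.07483	Small intestine/small bowel cancer
rs13151961	4	123115502	G	A	2.26e-5		7.43e-1	0.17515	Small intestine/small bowel cancer
rs1738074	6	159465977	C	T	-5.30e-5		3.15e-1	0.56542	Small intestine/small bowel cancer
rs17810546	3	159665050	G	A	1.73e-4		2.96e-2	0.12339	Small intestine/small bowel cancer
rs2327832	6	137973068	G	A	-1.87e-5		7.66e-1	0.22287	Small intestine/small bowel cancer
rs2816316	1	192536813	A	C	-1.32e-5		8.47e-1	0.81853	Small intestine/small bowel cancer
rs653178	12	112007756	T	C	7.96e-5		1.29e-1	0.51709	Small intestine/small bowel cancer
rs917997	2	103070568	C	T	-6.43e-5		3.06e-1	0.77487	Small intestine/small bowel cancer
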