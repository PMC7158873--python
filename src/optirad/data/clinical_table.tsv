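patient	age_at_surgery	scan_after_surgery_days	visual_assessment_after_surgery_days	gender	surgery	seizure_freedom	medication
Patient01	16.0	179	No data	F	L temporal lesionectomy	Yes	Keppra
Patient02	7.0	137	No data	M	L anterior temporal lobectomy	No	Phenytoin, sodium valproate and zonisamide
Patient03	7.0	236	No data	M	L anterior temporal lobectomy and amygdalo-hippocampectomy	Yes	Sodium valproate, lamotrigine
Patient04	13.0	100	267	F	L anterior temporal lobectomy and amygdalo-hippocampectomy	Yes	Oxcarbazepine, zonisamide
Patient05	15.0	167	No data	F	L anterior temporal lobectomy and amygdalo-hippocampectomy	Yes	Carbamazepine, sodium valproate, clobazam
Patient06	6.0	559	No data	F	L frontal, anterior temporal lobectomy and amygdalectomy	No	Lacosamide, phenobarbitone
Patient07	16.0	200	No data	M	L posterior temporal lesionectomy	Yes	Oxcarbazepine, sodim valproate, levetiracetam
Patient08	12.0	168	No data	M	L posterior temporal lesionectomy	Yes	Carbamazepine, clonazepam
Patient09	17.0	82	140	F	L temporal lesionectomy	Yes	Tegretol
Patient10	6.0	117	No data	M	L temporal lesionectomy	Yes	Levetiracetam, clobazam
Patient11	7.0	286	No data	F	L anterior temporal lesionectomy and amygdalo-hippocampectomy	No	Topiramate, clobazam
Patient12	18.0	102	320	M	L temporal lobectomy (extended)	No	Lamotrigine, lacosamide
Patient13	11.0	4	50	M	L temporal lobectomy and amygdalo-hippocampectomy (extended)	Yes	Carbamazepine, sodium valproate, levetiracetam
Patient14	12.0	158	161	M	L temporo-occipito-parietal disconnection	Yes	Perampanel, sodium valproate, levetiracetam
Patient15	12.0	89	98	M	L temporo-occipito-parietal disconnection	Yes	Carbamazepine, topiramate
Patient16	11.0	165	No data	M	L temporo-occipito-parietal disconnection	Yes	Carbamazepine, clobazam
Patient17	5.0	137	54	M	R fronto-temporo-parietal resection	Yes	Levetiracetam, clobazam
Patient18	14.0	81	64	F	R occipital lesionectomy	Yes	Sodium valproate, levetiracetam
Patient19	7.0	186	No data	F	R occipital lesionectomy	No	Sodium valproate, levetiracetam
Patient20	10.0	308	No data	F	R anterior temporal lobectomy and amygdalo-hippocampectomy	Yes	Sodium valproate, vigabatrin
Patient21	19.0	237	No data	F	R anterior temporal lobectomy	Yes	Oxcarbazepine
Patient22	12.0	411	264	M	R anterior temporal lobectomy and amygdalo-hippocampectomy	No	Oxcarbazepine, clobazam
Patient23	17.0	176	No data	M	R anterior temporal lobectomy and amygdalo-hippocampectomy	Yes	Levetiracetam
Patient24	7.0	160	No data	F	R anterior temporal lobectomy and amygdalo-hippocampectomy	No	Sodium valproate, lamotrigine, midazolam
Patient25	13.0	108	286	M	R temporal lesionectomy	Yes	–
Patient26	10.0	188	No data	F	R temporal lesionectomy	Yes	Levetiracetam
Patient27	6.0	287	No data	F	L temporal lesionectomy	Yes	Sodium valproate, lamotrigine
Patient28	11.0	242	No data	M	L parietal tumor resection	Yes	Zonisamide
Patient29	6.0	259	No data	F	R anterior temporal lesionectomy and amygdalo-hippocampectomy	Yes	Sodium valproate, topiramate
Patient30	6.0	154	No data	M	L temporal lobectomy	No	Topiramate, keppra
Patient31	5.0	176	111	F	R temporal lesionectomy	Yes	Keppra
Patient32	9.0	No data	333	M	L temporal lobectomy lesionectomy	No	Lacosamide, levetiracetam, lamotrigine, risperidone, phenytoin
Patient33	10.0	85	No data	F	L parietal lesionectomy	No	Sodium valproate, levetiracetam
Patient34	6.0	No data	No data	F	R occipital lobectomy	Yes	Keppra, lamotrigine
Patient35	13.0	89	No data	F	L temporal lobectomy and amygdalo-hippocampectomy	Yes	Carbamazepine
Patient36	8.0	No data	No data	M	R temporal lobectomy	No	Oxcarbazepine, lacosamide
Patient37	8.0	81	No data	M	L parietal lesionectomy	Unavailable	Sodium valproate, oxcarbazepine
Patient38	17.0	73	No data	F	R temporal lesionectomy and amygdalo-hippocampectomy	Unavailable	Keppra, oxcarbazepine, clobazam
Patient39	16.0	155	134	M	L temporo-occipito-parietal disconnection	Unavailable	Carbamazepine, lacosamide, phenobarbitone
Patient40	18.0	No data	No data	F	L temporal lesionectomy	Unavailable	Oxcarbazepine, midazolam
Patient41	18.0	No data	No data	F	L parietal lesionectomy	Unavailable	Topiramate, lamotrigine, levothyroxine
Patient42	5.0	125	239	M	R temporo-occipito-parietal disconnection	Unavailable	Carbamazepine
Patient43	15.0	102	299	F	L temporo-occipito-parietal disconnection	Unavailable	Lacosamide, levetiracetam, lamotrigine
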