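condition	siu_percent	us_incidence
HIV	6.17E+00	1.53E-04
Cancer	5.19E+00	5.37E-03
Diabetes mellitus	4.42E+00	6.13E-03
Herpes simplex	2.34E+00	2.50E-03
Arthritis	1.30E+00	4.10E-04
Atrial fibrillation	1.08E+00	6.45E-02
Gastroparesis	1.05E+00	2.50E-05
Heart failure	9.70E-01	1.77E-04
Schizophrenia	9.44E-01	7.00E-04
Crohn's disease	8.38E-01	7.90E-05
Dementia	7.69E-01	1.51E-03
Alzheimer's disease	7.53E-01	1.26E-03
Amyotrophic lateral sclerosis	6.04E-01	1.81E-05
Parkinson's disease	5.62E-01	1.77E-04
Breast cancer	5.04E-01	7.51E-04
Colitis	4.40E-01	8.80E-05
Asthma	4.19E-01	7.00E-04
Epilepsy	3.92E-01	4.70E-04
Lyme disease	3.45E-01	7.00E-05
Hepatitis C	3.08E-01	5.48E-05
Spina bifida	2.65E-01	3.49E-04
Leukemia	2.55E-01	1.69E-04
Hypothyroidism	2.33E-01	2.86E-04
Chronic pancreatitis	2.28E-01	4.35E-05
Celiac disease	2.17E-01	6.50E-05
Cardiomyopathy	1.96E-01	5.00E-05
Multiple myeloma	1.59E-01	7.76E-05
Lymphoma	1.48E-01	2.58E-04
Brain tumor	1.22E-01	7.54E-05
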