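phenotype	p_vntr_g	p_vntr_s
Height	6.01E-12	3.95E-15
FEV1-FVC ratio	1.56E-08	3.15E-08
Mean platelet volume	7.26E-07	3.12E-08
Platelet distribution width	1.87E-05	1.75E-05
Testosterone	0.0002	0.0005
Alcohol intake frequency	0.0002	0.0001
Basal metabolic rate	0.0005	0.0001
SHBG	0.001	0.002
Atherosclerosis-related	0.001	0.001
Platelet count	0.003	0.002
Mean corpuscular hemoglobin	0.02	0.2
Overall health rating	0.02	0.01
IGF-1	0.03	0.03
Lipoprotein-A	0.03	0.05
White blood cell count	0.04	0.05
Urate	0.05	0.03
Hemoglobin A1c	0.05	0.01
Aspartate aminotransferase	0.06	0.11
Eosinophil count	0.09	0.2
Waist-hip ratio	0.1	0.11
Alanine aminotransferase	0.11	0.1
Asthma	0.11	0.12
Mean sphered cell volume	0.13	0.66
Creatinine	0.13	0.34
Tanning (quantitative)	0.13	0.1
BMD Heel T-score	0.14	0.14
Total protein	0.16	0.13
Total bilirubin	0.16	0.33
RBC count	0.16	0.58
Sodium	0.17	0.16
Sodium in urine	0.17	0.16
Gamma glutamyltransferase	0.17	0.09
FVC	0.18	0.08
Cystatin-C	0.22	0.23
Calcium	0.24	0.15
RBC distribution width	0.27	0.57
Alkaline phosphatase	0.28	0.49
Corneal hysteresis	0.3	0.28
Lymphocyte count	0.31	0.24
Potassium in urine	0.34	0.26
Body mass index	0.34	0.3
Creatinine in urine	0.37	0.47
Apolipoprotein B	0.4	0.4
Apolipoprotein A	0.41	0.58
Direct bilirubin	0.41	0.58
Triglycerides	0.43	0.48
High light scatter reticulocyte count	0.48	0.22
LDL direct	0.49	0.53
Phosphate	0.53	0.43
C-reactive protein	0.55	0.68
Microalbumin in urine	0.6	0.38
Monocyte count	0.61	0.42
Autoimmune-related	0.64	0.56
Cholesterol	0.64	0.71
Glucose	0.69	0.93
Hair color	0.8	0.64
HDL cholesterol	0.91	0.99
Oestradiol higher than 212 pmol/L	0.91	0.82
Urea	0.92	0.79
Albumin	0.95	0.93
Rheumatoid factor higher than 16 U/mL	0.99	0.92
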