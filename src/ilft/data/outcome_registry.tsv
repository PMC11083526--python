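code	category	referral	description	comment_template
iL01	aetiological	phenotype_dependent	Possible alpha-1 antitrypsin deficiency	Serum A1AT {a1at} g/L is below 1.0 g/L, suggesting possible alpha-1 antitrypsin deficiency. Reflex A1AT phenotyping is recommended. Referral: dependent on phenotype.
iL02	descriptive	none	Abnormal ALT, ALP and GGT and a negative liver screen without significant fibrosis	ALT {alt} U/L, ALP {alp} U/L and GGT {ggt} U/L are elevated with a negative liver screen and no evidence of significant fibrosis. Review medication and lifestyle factors; repeat testing advised. Referral: not currently indicated.
iL04	aetiological	routine	ALD with significant fibrosis	The pattern suggests alcohol-related liver disease with significant fibrosis. Alcohol cessation support is advised. Referral: routine referral to the liver clinic is advised.
iL05	aetiological	none	ALD without significant fibrosis	The pattern suggests alcohol-related liver disease without significant fibrosis. Alcohol cessation support and repeat testing are advised. Referral: not currently indicated; manage in primary care.
iL06	aetiological	none	Likely Gilbert syndrome	Total bilirubin {bilirubin_total} umol/L with direct bilirubin {direct_bilirubin} umol/L indicates a predominantly unconjugated hyperbilirubinaemia, and haptoglobin {haptoglobin} g/L shows no evidence of haemolysis. This is consistent with Gilbert syndrome, a benign finding. Referral: not indicated.
iL15	descriptive	none	Abnormal ALT (<250 U/L) and a negative liver screen without significant fibrosis	ALT {alt} U/L is elevated with a negative liver screen and no evidence of significant fibrosis. Consider metabolic risk factors; repeat testing in primary care is advised. Referral: not currently indicated.
iL16	aetiological	routine	MASLD with significant fibrosis	The pattern suggests metabolic dysfunction-associated steatotic liver disease with significant fibrosis. Referral: routine referral to the liver clinic is advised.
iL17	aetiological	none	MASLD, simple steatosis without significant fibrosis	The pattern suggests metabolic dysfunction-associated steatotic liver disease without significant fibrosis. Lifestyle modification and cardiometabolic risk management are advised. Referral: not currently indicated; manage in primary care.
iL21	advisory	none	Mild, isolated elevation in ALP	ALP {alp} U/L is mildly elevated as an isolated finding. Potential causes include bone sources, drug reactions and MASLD. Recommend repeat ALP and GGT testing in three months. Referral: not currently indicated.
iL28	descriptive	none	Abnormal ALT and GGT and a negative liver screen without significant fibrosis	ALT {alt} U/L and GGT {ggt} U/L are elevated with a negative liver screen and no evidence of significant fibrosis. Review alcohol intake and hepatotoxic medication; repeat testing advised. Referral: not currently indicated.
iLX-NORMAL	advisory	none	Liver function tests within defined limits	All first-line liver analytes fall within the defined limits. No further laboratory testing has been cascaded. Referral: not indicated.
iLX-METALD-F	aetiological	routine	MetALD with significant fibrosis	The combination of alcohol excess and metabolic risk factors suggests MetALD with significant fibrosis. Referral: routine referral to the liver clinic is advised.
iLX-METALD-NF	aetiological	none	MetALD without significant fibrosis	The combination of alcohol excess and metabolic risk factors suggests MetALD without significant fibrosis. Alcohol reduction and cardiometabolic risk management are advised. Referral: not currently indicated; manage in primary care.
iLX-HBV	aetiological	routine	Positive hepatitis B serology	Hepatitis B serology is positive; confirmatory testing follows. Referral: routine referral for specialist assessment is advised.
iLX-HCV	aetiological	routine	Positive hepatitis C serology	Hepatitis C serology is positive; confirmatory testing follows. Referral: routine referral for specialist assessment is advised.
iLX-IRON	aetiological	routine	Possible haemochromatosis (raised transferrin saturation)	Transferrin saturation {transferrin_saturation}% is elevated, suggesting possible iron overload. HFE genotyping should be considered. Referral: routine referral is advised.
iLX-AUTOIMMUNE	aetiological	routine	Positive liver autoantibodies — possible autoimmune liver disease	Liver autoantibodies are positive, raising the possibility of autoimmune hepatitis, primary biliary cholangitis or systemic lupus erythematosus. Referral: routine referral for specialist assessment is advised.
iLX-WILSON	aetiological	routine	Low caeruloplasmin — possible Wilson disease	Caeruloplasmin {caeruloplasmin} g/L is low with a normal CRP in a patient under 45, raising the possibility of Wilson disease. Referral: routine referral for specialist assessment is advised.
iLX-CONJ-BILI	descriptive	routine	Conjugated hyperbilirubinaemia	Direct bilirubin {direct_bilirubin} umol/L of total {bilirubin_total} umol/L indicates a conjugated hyperbilirubinaemia, which requires further investigation of hepatobiliary causes. Referral: routine referral is advised.
iLX-HAEMOLYSIS	descriptive	routine	Possible haemolysis (low haptoglobin)	Haptoglobin {haptoglobin} g/L is low, suggesting possible haemolysis as the cause of the raised bilirubin. Haematological assessment is advised. Referral: routine referral is advised.
iLX-FIB-SIG	descriptive	routine	Abnormal liver tests with significant fibrosis	Fibrosis markers indicate significant liver fibrosis. Referral: routine referral to the liver clinic is advised.
iLX-FIB-INDET	descriptive	routine	Indeterminate fibrosis scores — fibrosis assessment advised	Indirect fibrosis scores fall in the indeterminate zone and no direct fibrosis marker is available to resolve them. Referral: routine referral for fibrosis assessment is advised.
iLX-ELF-URGENT	alert	urgent	Very high ELF score — urgent hepatology review advised	URGENT: the ELF score {elf} is 13 or higher, which carries a high short-term risk of hepatic decompensation. Referral: urgent referral for secondary care hepatology review is advised.
iLX-ALT-MARKED	alert	urgent	Markedly elevated ALT — possible acute liver injury	URGENT: ALT {alt} U/L is markedly elevated (250 U/L or higher), raising the possibility of acute liver injury. Referral: urgent assessment is advised.
iLX-MALIGNANCY	alert	routine	Elevated ALP with thrombocytosis — consider malignancy	The combination of ALP {alp} U/L and platelets {platelets} x10^9/L in a patient over 40 is associated with undiagnosed malignancy. Consider malignancy and request appropriate further tests (for example CT of the chest, abdomen and pelvis, or tests guided by symptoms or signs). Referral: routine further investigation is advised.
iLX-DESC	descriptive	routine	Abnormal liver tests with a negative liver screen — pattern not otherwise classified	The abnormal analytes ({abnormal_analytes}) do not match a specific pre-defined pattern and the liver screen is negative. Referral: routine referral is advised pending clinical review.
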