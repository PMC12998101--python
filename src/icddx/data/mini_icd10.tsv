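# Miniature ICD-10-like taxonomy (synthetic excerpt; four chapters, depth 5).
# Levels: chapter (1), block (2), category (3), subcategory4 (4), subcategory5 (5).
# The implicit virtual root "ROOT" (depth 0) joins the chapters.
code	parent	level	label
A00-B99	ROOT	chapter	Certain infectious and parasitic diseases
J00-J99	ROOT	chapter	Diseases of the respiratory system
K00-K95	ROOT	chapter	Diseases of the digestive system
R00-R99	ROOT	chapter	Symptoms, signs and abnormal clinical and laboratory findings
A00-A09	A00-B99	block	Intestinal infectious diseases
A15-A19	A00-B99	block	Tuberculosis
J09-J18	J00-J99	block	Influenza and pneumonia
J40-J47	J00-J99	block	Chronic lower respiratory diseases
K35-K38	K00-K95	block	Diseases of appendix
K55-K64	K00-K95	block	Other diseases of intestines
R10-R19	R00-R99	block	Symptoms and signs involving the digestive system and abdomen
R50-R69	R00-R99	block	General symptoms and signs
A00	A00-A09	category	Cholera
A02	A00-A09	category	Other salmonella infections
A15	A15-A19	category	Respiratory tuberculosis, bacteriologically and histologically confirmed
A16	A15-A19	category	Respiratory tuberculosis, not confirmed bacteriologically or histologically
J10	J09-J18	category	Influenza due to identified seasonal influenza virus
J18	J09-J18	category	Pneumonia, organism unspecified
J44	J40-J47	category	Other chronic obstructive pulmonary disease
J45	J40-J47	category	Asthma
K35	K35-K38	category	Acute appendicitis
K38	K35-K38	category	Other diseases of appendix
K56	K55-K64	category	Paralytic ileus and intestinal obstruction without hernia
K57	K55-K64	category	Diverticular disease of intestine
R10	R10-R19	category	Abdominal and pelvic pain
R19	R10-R19	category	Other symptoms and signs involving the digestive system and abdomen
R50	R50-R69	category	Fever of other and unknown origin
R56	R50-R69	category	Convulsions, not elsewhere classified
A00.0	A00	subcategory4	Cholera due to Vibrio cholerae 01, biovar cholerae
A00.1	A00	subcategory4	Cholera due to Vibrio cholerae 01, biovar eltor
A02.0	A02	subcategory4	Salmonella enteritis
A02.1	A02	subcategory4	Salmonella sepsis
A15.0	A15	subcategory4	Tuberculosis of lung, confirmed by sputum microscopy
A15.1	A15	subcategory4	Tuberculosis of lung, confirmed by culture only
A16.0	A16	subcategory4	Tuberculosis of lung, bacteriologically and histologically negative
A16.1	A16	subcategory4	Tuberculosis of lung, bacteriological and histological examination not done
J10.0	J10	subcategory4	Influenza with pneumonia, seasonal influenza virus identified
J10.1	J10	subcategory4	Influenza with other respiratory manifestations
J18.0	J18	subcategory4	Bronchopneumonia, unspecified
J18.9	J18	subcategory4	Pneumonia, unspecified
J44.0	J44	subcategory4	COPD with acute lower respiratory infection
J44.1	J44	subcategory4	COPD with acute exacerbation, unspecified
J45.0	J45	subcategory4	Predominantly allergic asthma
J45.1	J45	subcategory4	Nonallergic asthma
K35.2	K35	subcategory4	Acute appendicitis with generalized peritonitis
K35.8	K35	subcategory4	Other and unspecified acute appendicitis
K38.0	K38	subcategory4	Hyperplasia of appendix
K38.8	K38	subcategory4	Other specified diseases of appendix
K56.0	K56	subcategory4	Paralytic ileus
K56.1	K56	subcategory4	Intussusception
K57.2	K57	subcategory4	Diverticular disease of large intestine with perforation and abscess
K57.3	K57	subcategory4	Diverticular disease of large intestine without perforation or abscess
R10.0	R10	subcategory4	Acute abdomen
R10.4	R10	subcategory4	Other and unspecified abdominal pain
R19.0	R19	subcategory4	Intra-abdominal and pelvic swelling, mass and lump
R19.4	R19	subcategory4	Change in bowel habit
R50.2	R50	subcategory4	Drug-induced fever
R50.9	R50	subcategory4	Fever, unspecified
R56.0	R56	subcategory4	Febrile convulsions
R56.8	R56	subcategory4	Other and unspecified convulsions
K35.80	K35.8	subcategory5	Acute appendicitis, unspecified, without mention of peritonitis
K35.81	K35.8	subcategory5	Acute appendicitis, unspecified, with peritonitis
J45.10	J45.1	subcategory5	Nonallergic asthma, uncomplicated
J45.11	J45.1	subcategory5	Nonallergic asthma, with status asthmaticus
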