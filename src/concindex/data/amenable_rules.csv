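cause_label,place,timing,age_min,age_max,icd_patterns,exclusions
Intestinal infections,primary health care,primary prevention,1,14,A00-09,
"Diphtheria, Tetanus, Poliomyelitis, and Varicella",primary health care,primary prevention,1,74,A35-36;A80;B01,
Whooping cough,primary health care,primary prevention,1,14,A37,
Measles,primary health care,primary prevention,1,14,B05,
Rubella,primary health care,primary prevention,1,74,B06,
Scarlatina,primary health care,primary prevention,1,74,A38,
Meningococcus,primary health care,primary prevention,1,74,A39,
Erysipelas,primary health care,primary prevention,1,74,A46,
Legionellosis,primary health care,primary prevention,1,74,A48.1,
Malaria,primary health care,primary prevention,1,74,B50-54,
Streptococcal pharyngitis,primary health care,primary prevention,1,74,J02.0,
Cellulitis,primary health care,primary prevention,1,74,L03,
Tuberculosis,primary health care,early detection and treatment,1,74,A15-19;B90,
Malignant neoplasm of colon and rectum,primary health care,early detection and treatment,1,74,C18-21,
Melanoma of skin,primary health care,early detection and treatment,1,74,C43,
Malignant neoplasm of skin,primary health care,early detection and treatment,1,74,C44,
Malignant neoplasm of breast,primary health care,early detection and treatment,1,74,C50,
Malignant neoplasm of cervix uteri,primary health care,early detection and treatment,1,74,C53,
Malignant neoplasm of cervix uteri and body of uterus,primary health care,early detection and treatment,1,44,C54-55,
Malignant neoplasm of bladder,primary health care,early detection and treatment,1,74,C67,
Benign tumors,primary health care,early detection and treatment,1,74,D10-36,
Hypertensive disease,primary health care,early detection and treatment,1,74,I10-13;I15,
Cerebrovascular disease,primary health care,early detection and treatment,1,74,I60-69,
Diseases of the thyroid,primary health care,improved treatment and medical care,1,74,E00-07,
Diabetes mellitus,primary health care,improved treatment and medical care,1,49,E10-14,
Epilepsy,primary health care,improved treatment and medical care,1,74,G40-41,
All respiratory diseases (excl. pneumonia/influenza),primary health care,improved treatment and medical care,1,14,J00-09;J20-99,J09-18
Asthma,primary health care,improved treatment and medical care,15,49,J45-46,
COPD,primary health care,improved treatment and medical care,15,49,J40-44,
Septicemia,specialized health care,none,1,74,A40-41,
Malignant neoplasm of testis,specialized health care,none,1,74,C62,
Hodgkin's disease,specialized health care,none,1,74,C81,
Leukemia,specialized health care,none,1,44,C91-95,
Rheumatic and other valvular heart disease,specialized health care,none,1,74,I01-09,
Influenza,specialized health care,none,1,74,J09-11,
Pneumonia,specialized health care,none,1,74,J12-18,
Peptic ulcer,specialized health care,none,1,74,K25-28,
Appendicitis,specialized health care,none,1,74,K35-38,
Abdominal hernia,specialized health care,none,1,74,K40-46,
Cholelithiasis and cholecystitis,specialized health care,none,1,74,K80-81,
"Nephritis, nephrosis, and nephropathy",specialized health care,none,1,74,N00-09;N17-19;N25-27,
Obstructive uropathy and prostatic hyperplasia,specialized health care,none,1,74,N13;N20-21;N35;N40,
Maternal death,specialized health care,none,0,120,O00-99,
Congenital cardiovascular anomalies,specialized health care,none,1,74,Q20-28,
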