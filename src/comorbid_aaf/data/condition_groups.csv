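code,label,group,symptom_exempt,treatment_rule_applies
cancer,Cancer (incl. lymphoid/haematopoietic),cancer,0,1
myocardial_infarction,Myocardial infarction,cardiovascular,0,1
angina,Angina,cardiovascular,0,1
stroke,Stroke,cardiovascular,0,1
heart_failure,Heart failure,cardiovascular,0,1
lower_limb_arterial_disease,Lower limb arterial occlusive disease,cardiovascular,0,1
venous_insufficiency,Venous insufficiency,cardiovascular,0,1
high_blood_pressure,High blood pressure,cardiovascular,0,1
psoriasis,Psoriasis,dermatological,0,1
eczema,Eczema,dermatological,0,1
slough,Slough,dermatological,0,1
ulcer,Ulcer,digestive,0,1
cirrhosis,Cirrhosis and other liver diseases,digestive,0,1
food_allergies,Food allergies,digestive,0,1
diabetes_mellitus,Diabetes mellitus,endocrine,0,1
thyroid_disorder,Disorders of the thyroid gland,endocrine,0,1
obesity,Obesity (BMI >= 30),endocrine,1,0
back_pain,Back pain,musculoskeletal,1,0
neck_pain,Neck pain,musculoskeletal,1,0
scoliosis,Scoliosis,musculoskeletal,0,1
rheumatoid_arthritis,Rheumatoid arthritis,musculoskeletal,0,1
other_inflammatory_arthritis,Other inflammatory arthritis,musculoskeletal,0,1
knee_osteoarthritis,Knee osteoarthritis,musculoskeletal,0,1
hip_osteoarthritis,Hip osteoarthritis,musculoskeletal,0,1
other_osteoarthritis,Other osteoarthritis,musculoskeletal,0,1
osteoporosis,Osteoporosis,musculoskeletal,0,1
headache,Headache,neurological,1,0
epilepsy,Epilepsy,neurological,0,1
dementia,Dementia,neurological,0,1
parkinsons_disease,Parkinson's disease,neurological,0,1
multiple_sclerosis,Multiple sclerosis,neurological,0,1
other_neurological,Other unspecified neurological problems,neurological,0,1
depression,Depression,psychiatric,0,1
anxiety,Anxiety,psychiatric,0,1
autism,Autism,psychiatric,0,1
schizophrenia,Schizophrenia,psychiatric,0,1
trisomy_21,Trisomy 21,psychiatric,0,1
other_psychiatric,Other unspecified psychiatric impairments,psychiatric,0,1
asthma,Asthma,respiratory,0,1
chronic_bronchitis,Chronic bronchitis,respiratory,0,1
hay_fever,Hay fever,respiratory,0,1
cataract,Cataract,sensorial,0,1
strabismus,Strabismus,sensorial,0,1
glaucoma,Glaucoma,sensorial,0,1
eyesight_problem,Self-reported eyesight problem,sensorial,1,0
hearing_aid,Wearing a hearing aid,sensorial,1,0
hearing_problem,Self-reported hearing problem,sensorial,1,0
sequelae_of_injury,Sequelae of injury,sequelae_of_injury,0,1
urinary_incontinence,Urinary incontinence,urological,0,1
urinary_tract_infection,Infection of the urinary tract,urological,0,1
lithiasis,Lithiasis,urological,0,1
prostate_adenoma,Prostate adenoma,urological,0,1
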