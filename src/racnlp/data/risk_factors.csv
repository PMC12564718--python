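factor_id,name,synonyms
poor_appetite,poor appetite,reduced appetite|loss of appetite
weight_loss,weight loss,losing weight|wt loss
dysphagia,dysphagia,swallowing difficulty|difficulty swallowing
chewing_difficulty,chewing difficulty,difficulty chewing
dental_problems,dental problems,dental pain|tooth decay
ill_fitting_dentures,ill fitting dentures,loose dentures
dry_mouth,dry mouth,xerostomia
mouth_ulcers,mouth ulcers,oral ulcers
taste_changes,taste changes,altered taste
early_satiety,early satiety,
food_refusal,food refusal,refusing meals|refused meals
poor_oral_intake,poor oral intake,reduced oral intake
nausea,nausea,
vomiting,vomiting,emesis
diarrhoea,diarrhoea,loose stools
constipation,constipation,
dehydration,dehydration,poor fluid intake
malabsorption,malabsorption,
reflux,reflux,heartburn
dementia,dementia,cognitive decline
delirium,delirium,acute confusion
depression,depression,low mood
anxiety,anxiety,
cancer,cancer,malignancy
stroke,stroke,cva
parkinsons_disease,parkinsons disease,parkinsons
diabetes,diabetes,
copd,copd,emphysema
heart_failure,heart failure,cardiac failure
renal_disease,renal disease,kidney disease
liver_disease,liver disease,
thyroid_disorder,thyroid disorder,hypothyroidism
infection,infection,sepsis
pressure_injury,pressure injury,pressure sore
chronic_pain,chronic pain,persistent pain
polypharmacy,polypharmacy,
fatigue,fatigue,lethargy
frailty,frailty,frail
sarcopenia,sarcopenia,muscle wasting
immobility,immobility,bed bound
feeding_dependence,feeding dependence,requires feeding assistance
tremor,tremor,
social_isolation,social isolation,withdrawn
bereavement,bereavement,recent loss
alcohol_misuse,alcohol misuse,excess alcohol
anorexia,anorexia,
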