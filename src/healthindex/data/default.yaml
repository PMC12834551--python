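config_version: 1
eligibility_min_age: 18
frailty_min_age: 60
factors:
- bmi
- waist
- blood_pressure
- ldl
- glycaemia
- smoking
- alcohol
- family_history
- medical_history
- mental_health
- diet
- physical_activity
- frailty
domain_weights:
  physical_health: 0.2
  mental_health: 0.2
  diet: 0.2
  physical_activity: 0.2
  frailty: 0.2
physical_factor_weights:
  bmi: 1.0
  waist: 1.0
  blood_pressure: 1.0
  ldl: 1.0
  glycaemia: 1.0
  smoking: 1.0
  alcohol: 1.0
  family_history: 1.0
  medical_history: 1.0
points_map:
  low: 91.0
  moderate: 56.0
  high: 15.0
thresholds:
  healthy_min: 82
  at_risk_min: 31
  at_risk_max: 81
  poor_max: 30
domain_score_range:
- 0.0
- 100.0
asian_cutoffs: false
bmi_bands:
  underweight_max: 18.5
  overweight_min: 25.0
  obese_min: 30.0
bmi_bands_asian:
  underweight_max: 18.5
  overweight_min: 23.0
  obese_min: 27.5
waist_bands:
  male:
    moderate_min: 94.0
    high_min: 102.0
  female:
    moderate_min: 80.0
    high_min: 88.0
waist_bands_asian:
  male:
    moderate_min: 85.0
    high_min: 90.0
  female:
    moderate_min: 74.0
    high_min: 80.0
blood_pressure_bands:
  sbp_moderate: 120.0
  dbp_moderate: 80.0
  sbp_high: 140.0
  dbp_high: 90.0
ldl_bands:
  moderate_min: 2.6
  high_above: 4.1
glycaemia_bands:
  fbg_moderate: 5.6
  fbg_high: 7.0
  hba1c_moderate: 5.7
  hba1c_high: 6.5
alcohol_limits:
  weekly_male: 14.0
  weekly_female: 7.0
unsure_history_band: moderate
dass21:
  depression_cuts:
  - 9
  - 13
  - 20
  - 27
  anxiety_cuts:
  - 7
  - 9
  - 14
  - 19
  stress_cuts:
  - 14
  - 18
  - 25
  - 33
  high_if_at_least: severe
  moderate_if_at_least: mild
ipaq:
  met_vigorous: 8.0
  met_moderate: 4.0
  met_walking: 3.3
  daily_min_floor: 10.0
  daily_min_cap: 180.0
sfffq:
  fruit:
  - 1
  - 1
  - 2
  - 2
  - 3
  - 3
  vegetables:
  - 1
  - 1
  - 2
  - 2
  - 3
  - 3
  oily_fish:
  - 1
  - 2
  - 3
  - 3
  - 3
  - 3
  non_milk_sugar:
  - 3
  - 3
  - 2
  - 2
  - 1
  - 1
  fat:
  - 3
  - 3
  - 2
  - 2
  - 1
  - 1
  low_min_dqs: 12
  moderate_min_dqs: 8
frail:
  illness_threshold: 5
  illness_list_length: 11
advice:
  default_locale: en
  catalogs:
    en:
      bmi.moderate: Your BMI is in the overweight category. Being overweight puts
        you at risk of developing chronic diseases such as diabetes, hypertension,
        and coronary heart disease. Start adopting a healthy and active lifestyle
        before it's too late! Lowering your BMI starts with increasing your physical
        activity and sticking to a healthy eating plan.
      bmi.high: Your BMI is in the obese category, which strongly increases your risk
        of chronic diseases. Please discuss a weight-management plan with a health
        professional.
      waist.moderate: Your waist circumference is above the recommended level, a sign
        of central adiposity. Increasing activity and improving diet can reduce it.
      waist.high: Your waist circumference is substantially raised, which increases
        metabolic and cardiovascular risk. Consider seeking professional advice.
      blood_pressure.moderate: Your blood pressure is raised. Reducing salt intake,
        staying active and monitoring your readings can help bring it down.
      blood_pressure.high: Your blood pressure is in the hypertensive range (or you
        have been diagnosed with hypertension). Please follow up with your care provider.
      ldl.moderate: Your LDL cholesterol is borderline raised. A diet lower in saturated
        fat and regular exercise can improve it.
      ldl.high: Your LDL cholesterol is high (or you have been diagnosed with dyslipidemia).
        Please discuss lipid management with your doctor.
      glycaemia.moderate: Your blood glucose markers are in the prediabetic range.
        Lifestyle changes now can prevent progression to diabetes.
      glycaemia.high: Your blood glucose markers are in the diabetic range (or you
        have been diagnosed with type 2 diabetes). Please follow your care plan.
      smoking.moderate: As a former smoker you have already reduced your risk; staying
        smoke-free keeps it falling.
      smoking.high: Smoking is a leading cause of chronic disease. Quitting is the
        single most effective step you can take for your health.
      alcohol.moderate: You drink within the recommended limit. Keeping intake low,
        with alcohol-free days, protects your long-term health.
      alcohol.high: Your alcohol intake exceeds the recommended weekly limit, raising
        your risk of liver disease, cancer and high blood pressure. Consider cutting
        down.
      family_history.moderate: You have a family history of chronic disease. Regular
        screening and a healthy lifestyle are especially important for you.
      family_history.high: Your family history indicates elevated inherited risk;
        regular screening is strongly advised.
      medical_history.moderate: You are unsure of your medical history. A health screening
        would clarify your risk profile.
      medical_history.high: You have a diagnosed chronic condition. Keeping up with
        your care plan and healthy habits helps prevent complications.
      mental_health.moderate: Your questionnaire suggests mild to moderate emotional
        distress. Self-care, social support and stress management can help.
      mental_health.high: Your questionnaire suggests severe emotional distress. Please
        consider reaching out to a mental-health professional.
      diet.moderate: Your diet quality has room to improve. Aim for more fruit, vegetables
        and oily fish, and less sugar and fat-rich food.
      diet.high: Your diet quality is low, which contributes to chronic-disease risk.
        Small sustained changes — more fibre, less sugar and saturated fat — make
        a real difference.
      physical_activity.moderate: Your activity level is moderate. Building up towards
        higher weekly activity brings further health benefits.
      physical_activity.high: Your physical activity level is low. Even brisk walking
        most days of the week substantially reduces chronic-disease risk.
      frailty.moderate: You show early signs of frailty (pre-frail). Strength exercise
        and good nutrition can prevent progression.
      frailty.high: You screen as frail, which raises the risk of adverse health outcomes.
        Please discuss an assessment with your care provider.
    ms:
      bmi.moderate: BMI anda berada dalam kategori berlebihan berat badan. Mulakan
        gaya hidup sihat dan aktif sebelum terlambat!
      smoking.high: Merokok adalah punca utama penyakit kronik. Berhenti merokok adalah
        langkah paling berkesan untuk kesihatan anda.
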