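cohort,section,name,mean,sd
validation,meta,n,20,
validation,meta,n_events,192,
validation,meta,men_pct,50,
validation,subject,age_y,24.3,1.98
validation,subject,height_cm,169.0,7.69
validation,subject,weight_kg,62.7,9.10
validation,subject,bmi_kg_m2,21.8,1.92
validation,subject,skeletal_muscle_kg,27.4,6.32
validation,subject,percent_body_fat,22.0,7.69
validation,subject,waist_hip_ratio,0.8,0.04
validation,subject,basal_metabolism_kcal,1431.9,221.15
validation,subject,fasting_glucose_mg_dl,92.8,4.78
validation,nutrient,available_carbohydrate_g,37.9,17.65
validation,nutrient,fat_g,10.2,8.14
validation,nutrient,protein_g,8.5,5.81
validation,nutrient,fiber_g,2.8,2.86
development,meta,n,34,
development,meta,n_events,239,
development,meta,men_pct,50,
development,subject,age_y,23.2,2.11
development,subject,height_cm,168.6,7.27
development,subject,weight_kg,64.8,11.68
development,subject,bmi_kg_m2,22.7,3.44
development,subject,skeletal_muscle_kg,26.9,6.27
development,subject,percent_body_fat,21.3,9.33
development,subject,waist_hip_ratio,0.8,0.05
development,subject,basal_metabolism_kcal,1416.4,221.95
development,subject,fasting_glucose_mg_dl,92.7,5.05
development,nutrient,available_carbohydrate_g,47.6,20.32
development,nutrient,fat_g,9.4,6.27
development,nutrient,protein_g,11.6,6.47
development,nutrient,fiber_g,4.6,3.34
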