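# Identity dialect: source columns already carry canonical names and values;
# empty cells are missing.  This is the dialect the engine itself writes.
name: canonical
delimiter: ","
columns:
  record_id: record_id
  year: year
  residence_muni: residence_muni
  occurrence_muni: occurrence_muni
  facility_id: facility_id
  maternal_age: maternal_age
  race_color: race_color
  education: education
  prior_vaginal_births: prior_vaginal_births
  prior_cesarean_births: prior_cesarean_births
  plurality: plurality
  presentation: presentation
  gestational_age_weeks: gestational_age_weeks
  labour_onset: labour_onset
  delivery_mode: delivery_mode
  prenatal_visits: prenatal_visits
  prenatal_start_trimester: prenatal_start_trimester
  birthweight_g: birthweight_g
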