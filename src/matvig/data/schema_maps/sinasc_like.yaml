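# Example dialect for a SINASC-style live-birth extract: numeric-coded
# categorical variables, "9"/"99" ignored-value sentinels, semicolon
# delimiter, and 7-digit municipality codes with a trailing check digit.
# Adapt column names and recodes to the vintage of the extract at hand.
name: sinasc_like
delimiter: ";"
strip_geo_check_digit: true
columns:
  CONTADOR: record_id
  ANO: year
  CODMUNRES: residence_muni
  CODMUNNASC: occurrence_muni
  CODESTAB: facility_id
  IDADEMAE: maternal_age
  RACACORMAE: race_color
  ESCMAE: education
  QTDPARTNOR: prior_vaginal_births
  QTDPARTCES: prior_cesarean_births
  GRAVIDEZ: plurality
  TPAPRESENT: presentation
  SEMAGESTAC: gestational_age_weeks
  STTRABPART: labour_onset
  PARTO: delivery_mode
  CONSULTAS: prenatal_visits
  MESPRENAT: prenatal_start_trimester
  PESO: birthweight_g
missing_sentinels:
  maternal_age: ["99"]
  gestational_age_weeks: ["99"]
  prior_vaginal_births: ["99"]
  prior_cesarean_births: ["99"]
  prenatal_visits: ["99"]
  birthweight_g: ["9999"]
value_maps:
  race_color:
    "1": white
    "2": black
    "3": asian
    "4": brown
    "5": indigenous
    "9": null
  education:
    "1": none
    "2": "1-3"
    "3": "4-7"
    "4": "8-11"
    "5": "12+"
    "9": null
  plurality:
    "1": single
    "2": multiple
    "3": multiple
    "9": null
  presentation:
    "1": cephalic
    "2": breech
    "3": transverse_oblique
    "9": null
  labour_onset:
    "1": spontaneous
    "2": induced
    "3": cesarean_before_labour
    "9": null
  delivery_mode:
    "1": vaginal
    "2": cesarean
    "9": null
  prenatal_start_trimester:
    "1": "1"
    "2": "2"
    "3": "3"
    "9": null
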