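# Default code lists for flagging severe maternal morbidity
# ("potentially life-threatening conditions") in public obstetric
# hospitalization records.
#
# This is an EDITABLE DEFAULT covering the classic PLTC groups —
# severe hypertensive, hemorrhagic and infectious complications plus
# severe-management markers — not an official or exhaustive list.
# Codes are ICD-10 prefixes, matched dot-free and case-insensitively:
# "O15" matches O150, O151, O159, ...
cause_code_sets:
  hypertension:
    - O141      # severe pre-eclampsia
    - O15       # eclampsia
  hemorrhage:
    - O441      # placenta praevia with haemorrhage
    - O45       # premature separation of placenta
    - O46       # antepartum haemorrhage NEC
    - O67       # intrapartum haemorrhage
    - O72       # postpartum haemorrhage
  infection:
    - O85       # puerperal sepsis
    - O86       # other puerperal infections
    - A41       # other sepsis

# Procedure-code stubs for severe surgical management (hysterectomy,
# laparotomy); replace with the full local procedure table in production.
surgical_procedure_codes:
  - "0409060160"   # puerperal hysterectomy (stub)
  - "0407040242"   # exploratory laparotomy (stub)

# Management criteria
icu_criterion_days: 1       # ICU admission: icu_days >= 1
prolonged_stay_days: 7      # prolonged stay: length of stay strictly > 7 days
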