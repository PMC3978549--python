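{
  "version": 1,
  "table1": {
    "title": "Age distribution for women (n=40) and men (n=45) patients reporting age",
    "denominators": {"female": 40, "male": 45},
    "rows": [
      ["0-17", 2, 1],
      ["18-29", 9, 5],
      ["30-44", 16, 8],
      ["45-64", 8, 19],
      ["65-75", 3, 8],
      ["76-84", 0, 3],
      ["85+", 2, 1]
    ]
  },
  "table2": {
    "title": "Profiles of narrators for women (n=100) and men (n=91) patients",
    "sections": [
      {"name": "narrator", "denominators": {"female": 100, "male": 91},
       "rows": [["first", 52, 45], ["third", 48, 46]], "printed_p": ".72"},
      {"name": "witness", "denominators": {"female": 48, "male": 46},
       "rows": [["yes", 19, 21], ["no", 29, 25]], "printed_p": ".55"},
      {"name": "relationship_relative", "denominators": {"female": 40, "male": 38},
       "rows": [["adult_child", 24, 15], ["other_relative", 10, 5], ["spouse", 6, 18]],
       "printed_p": ".008"},
      {"name": "relationship_nonrelative", "denominators": {"female": 8, "male": 8},
       "rows": [["friend", 2, 3], ["stranger", 6, 5]], "printed_p": null}
    ]
  },
  "table3": {
    "title": "Stroke symptoms reported for women (n=91) and men (n=83) patients",
    "denominators": {"female": 91, "male": 83},
    "rows": [
      ["hemiparesis", 68, 63, ".86"],
      ["impaired_speech_or_comprehension", 59, 47, ".27"],
      ["visual_disturbance", 11, 5, ".17"],
      ["ataxia_discoordination", 16, 11, ".43"],
      ["vertigo", 13, 13, ".80"],
      ["balance_difficulty", 7, 8, ".65"],
      ["pain_excl_headache", 5, 5, ".88"],
      ["mental_status_change", 39, 27, ".16"],
      ["headache", 16, 11, ".62"],
      ["lightheadedness", 5, 3, ".55"],
      ["other_neurologic", 13, 9, ".67"],
      ["nonneurologic", 4, 5, ".63"]
    ],
    "hemiparesis_subtype": {
      "denominators": {"female": 68, "male": 63},
      "rows": [["body", 30, 33], ["face", 2, 4], ["both", 36, 26]],
      "printed_p": ".33"
    }
  },
  "table4": {
    "title": "Reports of mental status change for women (n=91) and men (n=83) patients by narrator",
    "sections": [
      {"name": "first", "denominators": {"female": 48, "male": 44},
       "rows": [["yes", 27, 16], ["no", 21, 28]], "printed_p": ".056"},
      {"name": "third", "denominators": {"female": 43, "male": 39},
       "rows": [["yes", 12, 11], ["no", 31, 28]], "printed_p": ".97"}
    ]
  },
  "table5": {
    "title": "Reports of nontraditional symptoms (excluding mental status change) for women (n=91) and men (n=82) patients by narrator",
    "sections": [
      {"name": "first", "denominators": {"female": 48, "male": 44},
       "rows": [["ge1", 22, 19], ["none", 26, 25]], "printed_p": ".80"},
      {"name": "third", "denominators": {"female": 43, "male": 39},
       "rows": [["ge1", 12, 9], ["none", 31, 30]], "printed_p": ".62"}
    ]
  },
  "table6": {
    "title": "Reports of stroke symptoms by ischemic (n=67) and hemorrhagic (n=29) stroke",
    "denominators": {"ischemic": 67, "hemorrhagic": 29},
    "rows": [
      ["hemiparesis", 56, 20, ".11"],
      ["impaired_speech_or_comprehension", 42, 19, ".79"],
      ["visual_disturbance", 8, 3, ".82"],
      ["ataxia_discoordination", 13, 2, ".12"],
      ["vertigo", 18, 1, ".01"],
      ["balance_difficulty", 5, 2, ".92"],
      ["pain_excl_headache", 3, 4, ".11"],
      ["mental_status_change", 21, 14, ".11"],
      ["headache", 7, 11, ".002"],
      ["lightheadedness", 5, 0, ".13"],
      ["other_neurologic", 10, 5, ".77"],
      ["nonneurologic", 5, 2, ".92"]
    ],
    "hemiparesis_subtype": {
      "denominators": {"ischemic": 56, "hemorrhagic": 20},
      "rows": [["body", 19, 9], ["face", 5, 0], ["both", 32, 11]],
      "printed_p": ".30"
    }
  },
  "in_text": {
    "n_relevant": 191,
    "n_irrelevant": 244,
    "n_skipped": 281,
    "n_female_all": 100,
    "n_male_all": 91,
    "n_symptom_stories": 174,
    "n_female_symptom": 91,
    "n_male_symptom": 83,
    "n_first_person": 97,
    "n_third_person": 94,
    "n_first_person_symptom": 92,
    "n_third_person_symptom": 82,
    "n_ischemic": 67,
    "n_hemorrhagic": 29,
    "classifier_precision": 0.66,
    "classifier_recall": 0.5,
    "coder_agreement_percent": 83,
    "msc_by_narrator": {
      "rows": [["first", 43, 49], ["third", 23, 59]], "printed_p": ".01"
    },
    "nontrad_excl_msc_by_narrator": {
      "rows": [["first", 41, 51], ["third", 21, 61]], "printed_p": ".006"
    },
    "any_nontrad_by_stroke_type": {
      "rows": [["ischemic", 36, 31], ["hemorrhagic", 23, 6]], "printed_p": ".001"
    },
    "delay_by_sex": {
      "rows": [["female", 35, 45], ["male", 24, 52]], "printed_p": ".12"
    }
  }
}
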