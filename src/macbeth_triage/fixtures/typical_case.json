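{
  "case_id": "typical_case",
  "provenance": "Typical case defined by the Bauru expert panel: severe bodily injuries, mild genital injuries, STI contamination, no pregnancy diagnosis, moderate depression and phobic anxiety disorder, death threat, no protective family figure. The pregnancy criterion's evaluation was not reported and is therefore omitted here.",
  "assignments": {
    "bodily_injury": "serious",
    "genital_injury": "bruise_hematoma",
    "stis": "diagnosis",
    "depression": "moderate",
    "phobic_anxiety": "moderate",
    "threat": "death",
    "family_aspect": "no_protective_figure"
  }
}
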