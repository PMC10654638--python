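{
  "emotional disorder": [
    "emotional distress",
    "confusional state",
    "depression",
    "depressed mood",
    "suicidal ideation",
    "personality disorder",
    "amnesia",
    "abasia",
    "mental disorder",
    "emotional disorder",
    "disturbance in attention",
    "suicide attempt",
    "mood altered",
    "depression suicidal"
  ],
  "cardiac disorders": [
    "tachycardia",
    "cardiac failure congestive",
    "arrhythmia",
    "palpitations",
    "left ventricular dysfunction",
    "cardiomegaly",
    "cardiac disorder",
    "cardiac failure",
    "myocardial infarction",
    "atrial fibrillation",
    "heart rate decreased",
    "cardio-respiratory arrest",
    "cardiovascular disorder",
    "cardiac discomfort"
  ]
}
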