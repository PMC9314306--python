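{
  "name": "E-RS:COPD",
  "description": "Evaluating Respiratory Symptoms in COPD daily diary: 11 ordinal items summed to the RS-Total score (range 0-40).",
  "items": [
    {"item_id": 1, "label": "Congestion", "construct": "Chest Symptoms", "max_score": 4},
    {"item_id": 2, "label": "Cough frequency", "construct": "Cough and Sputum", "max_score": 4},
    {"item_id": 3, "label": "Mucus quantity", "construct": "Cough and Sputum", "max_score": 3},
    {"item_id": 4, "label": "Difficulty with mucus", "construct": "Cough and Sputum", "max_score": 4},
    {"item_id": 5, "label": "Discomfort", "construct": "Chest Symptoms", "max_score": 4},
    {"item_id": 6, "label": "Tightness", "construct": "Chest Symptoms", "max_score": 4},
    {"item_id": 7, "label": "Breathless today", "construct": "Breathlessness", "max_score": 4},
    {"item_id": 8, "label": "Breathless with activity", "construct": "Breathlessness", "max_score": 3},
    {"item_id": 9, "label": "Short of breath - personal care", "construct": "Breathlessness", "max_score": 4},
    {"item_id": 10, "label": "Short of breath - indoor activities", "construct": "Breathlessness", "max_score": 3},
    {"item_id": 11, "label": "Short of breath - outdoor activities", "construct": "Breathlessness", "max_score": 3}
  ]
}
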