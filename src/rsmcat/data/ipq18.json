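{
  "name": "IPQ-18",
  "n_categories": 5,
  "thresholds": [-3.76, -1.91, 1.57, 4.11],
  "metadata": {
    "description": "18-item inpatient perception questionnaire, anchored Rasch rating scale calibration",
    "reliability": 0.94,
    "pop_mean": 2.64,
    "pop_sd": 2.09
  },
  "items": [
    {"id": "39", "category": "L", "text": "Did staff tell you about medication side effects when going home?", "delta": 3.78, "steps": [0.02, 1.87, 5.35, 7.89]},
    {"id": "41", "category": "L", "text": "Did doctors or nurses give your family information needed to help you?", "delta": 2.76, "steps": [-1.00, 0.85, 4.33, 6.87]},
    {"id": "27", "category": "N", "text": "Did hospital staff talk about your worries and fears?", "delta": 2.22, "steps": [-1.54, 0.31, 3.79, 6.33]},
    {"id": "11", "category": "W", "text": "Were you ever bothered by noise at night from other patients?", "delta": 1.58, "steps": [-2.18, -0.33, 3.15, 5.69]},
    {"id": "24", "category": "N", "text": "Were you involved in decisions about your care and treatment?", "delta": 0.67, "steps": [-3.09, -1.24, 2.24, 4.78]},
    {"id": "30", "category": "N", "text": "How long was it after using the call button before you got the help you needed?", "delta": 0.42, "steps": [-3.34, -1.49, 1.99, 4.53]},
    {"id": "42", "category": "L", "text": "Did staff tell you how to contact them if worries arose after leaving?", "delta": -0.30, "steps": [-4.06, -2.21, 1.27, 3.81]},
    {"id": "9", "category": "A", "text": "Did you feel you waited a long time to get to a bed on a ward?", "delta": -0.63, "steps": [-4.39, -2.54, 0.94, 3.48]},
    {"id": "44", "category": "O", "text": "How would you rate how well the doctors and nurses worked together?", "delta": -0.71, "steps": [-4.47, -2.62, 0.86, 3.40]},
    {"id": "2", "category": "A", "text": "How organized was the care you received in the emergency room?", "delta": -0.95, "steps": [-4.71, -2.86, 0.62, 3.16]},
    {"id": "5", "category": "A", "text": "Were you given enough notice of your date of admission?", "delta": -1.08, "steps": [-4.84, -2.99, 0.49, 3.03]},
    {"id": "12", "category": "W", "text": "Were you bothered by noise at night from hospital staff?", "delta": -1.10, "steps": [-4.86, -3.01, 0.47, 3.01]},
    {"id": "17", "category": "D", "text": "Did you have confidence and trust in the doctors treating you?", "delta": -1.10, "steps": [-4.86, -3.01, 0.47, 3.01]},
    {"id": "23", "category": "N", "text": "Did staff say one thing and something quite different happened to you?", "delta": -1.10, "steps": [-4.86, -3.01, 0.47, 3.01]},
    {"id": "38", "category": "L", "text": "Did staff explain the purpose of the medicines so that you could understand?", "delta": -1.10, "steps": [-4.86, -3.01, 0.47, 3.01]},
    {"id": "18", "category": "D", "text": "Did doctors talk in front of you as if you weren't there?", "delta": -1.12, "steps": [-4.88, -3.03, 0.45, 2.99]},
    {"id": "19", "category": "N", "text": "Did you get answers that you could understand from a nurse?", "delta": -1.12, "steps": [-4.88, -3.03, 0.45, 2.99]},
    {"id": "34", "category": "P", "text": "Did hospital staff do everything they could to help you control your pain?", "delta": -1.12, "steps": [-4.88, -3.03, 0.45, 2.99]}
  ]
}
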