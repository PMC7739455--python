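{
  "name": "ischemic-stroke-thrombolysis",
  "alphabet": [
    "CT examination",
    "MRI examination",
    "admit",
    "anticoagulant drugs",
    "antiplatelet drugs",
    "antipyretic",
    "blood glucose test",
    "discharge",
    "dispensing drugs",
    "have a fever",
    "heparin injection",
    "hypertensive",
    "insulin injection",
    "statins drugs",
    "thrombolysis",
    "vital_signs test"
  ],
  "rules": [
    {
      "id": "1.1",
      "label": "1",
      "description": "Before IV thrombolysis, CT should be tested",
      "mandatory": true,
      "any_of": [
        {"template": "precedence", "A": "CT examination", "T": "thrombolysis", "psi": []}
      ]
    },
    {
      "id": "1.2",
      "label": "1",
      "description": "Before IV thrombolysis, blood glucose should be tested",
      "mandatory": true,
      "any_of": [
        {"template": "precedence", "A": "blood glucose test", "T": "thrombolysis", "psi": []}
      ]
    },
    {
      "id": "2",
      "label": "2",
      "description": "The door-to-needle time (DNT) should be within 60 min",
      "mandatory": true,
      "any_of": [
        {
          "template": "precedence",
          "A": "admit",
          "T": "thrombolysis",
          "psi": [{"i": 1, "j": 1, "text": "[complete time, complete time, 60, <]"}]
        }
      ]
    },
    {
      "id": "3",
      "label": "3",
      "description": "BP need to be kept less than 180/100 mm Hg",
      "mandatory": true,
      "any_of": [
        {
          "template": "precedence",
          "A": "vital_signs test",
          "T": "antipyretic",
          "psi": [{"i": 3, "text": "[systolic pressure, 180, <]&[diastolic pressure, 100, <]"}]
        }
      ]
    },
    {
      "id": "4",
      "label": "4",
      "description": "No IV alteplase after a treatment dose of low-molecular-weight heparin within the previous 24 h",
      "mandatory": true,
      "any_of": [
        {"template": "not_coexistence", "A": "heparin injection", "T": "thrombolysis", "psi": []},
        {
          "template": "precedence",
          "A": "heparin injection",
          "T": "thrombolysis",
          "psi": [{"i": 1, "j": 1, "text": "[complete time, start time, 24*60, >]"}]
        }
      ]
    },
    {
      "id": "5",
      "label": "5",
      "description": "For dispensing drugs, at least two nurses should execute a double check",
      "mandatory": true,
      "any_of": [
        {
          "template": "existence",
          "A": "dispensing drugs",
          "psi": [{"i": 6, "j": 6, "text": "[executor, proofreader, !=]"}]
        }
      ]
    }
  ]
}
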