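{
  "name": "well-being-cross-scale-loop",
  "provenance": "Published sub-diagram: a six-variable cross-scale reinforcing loop through well-being (four negative and two positive connections), spanning the psychological, behavioral, social and biological domains. Edge polarities transcribed from the narrative description of the loop.",
  "variables": [
    {
      "id": "well-being",
      "label": "Well-being",
      "domain": "psychological",
      "definition": "Overall sense of well-being encompassing physical, emotional, social and spiritual dimensions (assigned to one domain for scale classification)."
    },
    {
      "id": "maladaptive-cognitive-emotion-regulation",
      "label": "Maladaptive cognitive emotion regulation",
      "domain": "psychological",
      "definition": "Unhelpful emotion-regulation strategies such as low impulse control and blaming others."
    },
    {
      "id": "prosocial-behavior",
      "label": "Prosocial behavior",
      "domain": "behavioral",
      "definition": "Voluntary behavior intended to benefit others."
    },
    {
      "id": "loneliness",
      "label": "Loneliness",
      "domain": "social",
      "definition": "Perceived lack of meaningful social connection."
    },
    {
      "id": "smoking",
      "label": "Smoking",
      "domain": "behavioral",
      "definition": "Cigarette smoking / nicotine use."
    },
    {
      "id": "physical-health",
      "label": "Physical health",
      "domain": "biological",
      "definition": "Overall somatic health status."
    }
  ],
  "connections": [
    {"source": "well-being", "target": "maladaptive-cognitive-emotion-regulation", "polarity": "negative", "mechanism_note": "Lower well-being increases reliance on maladaptive emotion-regulation strategies.", "references": [], "proposer_count": 0},
    {"source": "maladaptive-cognitive-emotion-regulation", "target": "prosocial-behavior", "polarity": "negative", "mechanism_note": "Poor emotion regulation diminishes prosocial behavior.", "references": [], "proposer_count": 0},
    {"source": "prosocial-behavior", "target": "loneliness", "polarity": "negative", "mechanism_note": "Less prosocial behavior reduces the quality and depth of social interactions, fostering loneliness.", "references": [], "proposer_count": 0},
    {"source": "loneliness", "target": "smoking", "polarity": "positive", "mechanism_note": "Loneliness encourages addictive behaviors such as smoking as a coping mechanism.", "references": [], "proposer_count": 0},
    {"source": "smoking", "target": "physical-health", "polarity": "negative", "mechanism_note": "Smoking harms physical health, e.g. raising cancer risk.", "references": [], "proposer_count": 0},
    {"source": "physical-health", "target": "well-being", "polarity": "positive", "mechanism_note": "Physical health is an important determinant of well-being.", "references": [], "proposer_count": 0}
  ]
}
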