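{
  "name": "sleep-depression-smoking-triad",
  "provenance": "Published sub-diagram: the fully bidirectional triad of sleep disturbance, affective symptoms of depression, and smoking (all six directed connections, all positive), illustrating feedback loops of lengths two and three.",
  "variables": [
    {
      "id": "affective-symptoms-of-depression",
      "label": "Affective symptoms of depression",
      "domain": "psychological",
      "definition": "Mood-related depressive symptoms such as low mood and anhedonia."
    },
    {
      "id": "sleep-disturbance",
      "label": "Sleep disturbance",
      "domain": "behavioral",
      "definition": "Problems initiating or maintaining sleep, or non-restorative sleep."
    },
    {
      "id": "smoking",
      "label": "Smoking",
      "domain": "behavioral",
      "definition": "Cigarette smoking / nicotine use."
    }
  ],
  "connections": [
    {"source": "affective-symptoms-of-depression", "target": "sleep-disturbance", "polarity": "positive", "mechanism_note": "Mood alterations disrupt sleep regulation.", "references": [], "proposer_count": 0},
    {"source": "affective-symptoms-of-depression", "target": "smoking", "polarity": "positive", "mechanism_note": "Depressive symptoms can increase smoking frequency as a form of coping.", "references": [], "proposer_count": 0},
    {"source": "sleep-disturbance", "target": "affective-symptoms-of-depression", "polarity": "positive", "mechanism_note": "Disturbed sleep exacerbates depressive symptoms.", "references": [], "proposer_count": 0},
    {"source": "sleep-disturbance", "target": "smoking", "polarity": "positive", "mechanism_note": "Nicotine may be used to counteract daytime sleepiness.", "references": [], "proposer_count": 0},
    {"source": "smoking", "target": "affective-symptoms-of-depression", "polarity": "positive", "mechanism_note": "Nicotine's neurochemical effects raise the risk of depressive symptoms.", "references": [], "proposer_count": 0},
    {"source": "smoking", "target": "sleep-disturbance", "polarity": "positive", "mechanism_note": "As a stimulant, nicotine hinders falling asleep and degrades sleep quality.", "references": [], "proposer_count": 0}
  ]
}
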