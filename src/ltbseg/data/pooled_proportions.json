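{
  "description": "Pooled proportion-correct values and design trial counts from the published masking experiment (nine observers; 200 trials per masking condition each, of which the congruent condition splits into 100 in-phase and 100 opposite-phase trials).",
  "design": {
    "n_observers": 9,
    "trials_per_condition": 200,
    "trials_per_phase": 100
  },
  "pooled_proportion_correct": {
    "neu": 0.8217,
    "con": 0.8622,
    "inc": 0.8189,
    "con_0": 0.8944,
    "con_180": 0.8300
  },
  "comparisons": [
    {"name": "neu_con_inc", "conditions": ["neu", "con", "inc"]},
    {"name": "neu_vs_con0", "conditions": ["neu", "con_0"]},
    {"name": "con0_vs_con180", "conditions": ["con_0", "con_180"]},
    {"name": "neu_vs_inc", "conditions": ["neu", "inc"]},
    {"name": "neu_vs_con180", "conditions": ["neu", "con_180"]}
  ]
}
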