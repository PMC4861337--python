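# Synthetic panel emulating a 25-member technical interest group of whom 18
# respond; roughly one responder in nine stops before the end of the survey.
n_invited: 25
n_experts: 18
partial_completion_rate: 0.111
consensus: 0.35
seed: 2016
probs:
  default: [0.55, 0.20, 0.15, 0.10]
  themes:
    "public health research": [0.75, 0.10, 0.10, 0.05]
    "burden": [0.40, 0.30, 0.20, 0.10]
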