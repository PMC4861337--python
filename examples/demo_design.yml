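questions:
  - id: Q1
    text: "Incidence of wasting over time in different contexts"
    theme: "burden"
  - id: Q2
    text: "Global burden of concurrent wasting and stunting"
    theme: "burden"
  - id: Q3
    text: "Role of pre-pregnancy nutritional status in growth deficits at birth"
    theme: "risk factors"
  - id: Q4
    text: "Does treatment of wasting support catch-up in linear growth"
    theme: "existing interventions"
  - id: Q5
    text: "Optimal therapeutic food formulation for ponderal and linear growth"
    theme: "clinical research"
  - id: Q6
    text: "Catch-up in height from interventions outside the 1000 days"
    theme: "public health research"
criteria:
  - id: answerability
    text: "Is the question well framed and likely to gain ethical approval?"
  - id: usefulness
    text: "Would the resulting intervention be deliverable, effective, efficacious?"
  - id: impact
    text: "Could reaching the endpoints remove 5%+ of burden, benefiting the most underprivileged?"
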