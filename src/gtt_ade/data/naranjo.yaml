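# Naranjo adverse drug reaction probability scale (Naranjo et al., 1981):
# ten questions, each answered yes / no / unknown ("do not know"), with the
# published item weights. The total score maps onto four causality
# categories; only "definite" and "probable" events enter the analysis.
items:
  - question: Are there previous conclusive reports on this reaction?
    "yes": 1
    "no": 0
    unknown: 0
  - question: Did the adverse event appear after the suspected drug was administered?
    "yes": 2
    "no": -1
    unknown: 0
  - question: Did the adverse reaction improve when the drug was discontinued or a
      specific antagonist was administered?
    "yes": 1
    "no": 0
    unknown: 0
  - question: Did the adverse reaction reappear when the drug was readministered?
    "yes": 2
    "no": -1
    unknown: 0
  - question: Are there alternative causes that could on their own have caused the
      reaction?
    "yes": -1
    "no": 2
    unknown: 0
  - question: Did the reaction reappear when a placebo was given?
    "yes": -1
    "no": 1
    unknown: 0
  - question: Was the drug detected in the blood at concentrations known to be toxic?
    "yes": 1
    "no": 0
    unknown: 0
  - question: Was the reaction more severe when the dose was increased, or less severe
      when the dose was decreased?
    "yes": 1
    "no": 0
    unknown: 0
  - question: Did the patient have a similar reaction to the same or similar drugs in
      any previous exposure?
    "yes": 1
    "no": 0
    unknown: 0
  - question: Was the adverse event confirmed by any objective evidence?
    "yes": 1
    "no": 0
    unknown: 0
categories:
  definite: 9      # score >= 9
  probable: 5      # 5 <= score <= 8
  possible: 1      # 1 <= score <= 4
  doubtful: null   # score <= 0
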