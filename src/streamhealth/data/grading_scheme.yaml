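# Five-class river-health grading criteria for the macroinvertebrate indices,
# version 1. Intervals are right-closed as printed, "(a, b]"; the top class is
# open above and the bottom class is closed at its printed lower bound so the
# scheme is total over each index's attainable range. Two gaps in the printed
# criteria are resolved by extending the LOWER class (so a gap can never raise
# a site's grade); the resolutions are recorded under gap_resolutions.
version: 1
gap_resolutions:
  aspt: "no class on (3.0, 3.1]; Fair extended downward to (3.0, 3.5]"
  ept: "no class on (27, 28]; Good extended upward to (20, 28]"
schemes:
  h_prime:
    direction: higher_is_better
    classes:
      - {label: Excellent, lower: 3.0, upper: .inf, lower_closed: false, upper_closed: false}
      - {label: Good, lower: 2.0, upper: 3.0, lower_closed: false, upper_closed: true}
      - {label: Fair, lower: 1.0, upper: 2.0, lower_closed: false, upper_closed: true}
      - {label: Poor, lower: 0.5, upper: 1.0, lower_closed: false, upper_closed: true}
      - {label: Very poor, lower: 0.0, upper: 0.5, lower_closed: true, upper_closed: true}
  bmwp:
    direction: higher_is_better
    classes:
      - {label: Excellent, lower: 80.0, upper: .inf, lower_closed: false, upper_closed: false}
      - {label: Good, lower: 50.0, upper: 80.0, lower_closed: false, upper_closed: true}
      - {label: Fair, lower: 25.0, upper: 50.0, lower_closed: false, upper_closed: true}
      - {label: Poor, lower: 10.0, upper: 25.0, lower_closed: false, upper_closed: true}
      - {label: Very poor, lower: 0.0, upper: 10.0, lower_closed: true, upper_closed: true}
  aspt:
    direction: higher_is_better
    classes:
      - {label: Excellent, lower: 4.0, upper: .inf, lower_closed: false, upper_closed: false}
      - {label: Good, lower: 3.5, upper: 4.0, lower_closed: false, upper_closed: true}
      - {label: Fair, lower: 3.0, upper: 3.5, lower_closed: false, upper_closed: true}
      - {label: Poor, lower: 2.0, upper: 3.0, lower_closed: false, upper_closed: true}
      - {label: Very poor, lower: 0.0, upper: 2.0, lower_closed: true, upper_closed: true}
  bi:
    direction: lower_is_better
    classes:
      - {label: Excellent, lower: 0.0, upper: 3.5, lower_closed: true, upper_closed: true}
      - {label: Good, lower: 3.5, upper: 5.5, lower_closed: false, upper_closed: true}
      - {label: Fair, lower: 5.5, upper: 6.5, lower_closed: false, upper_closed: true}
      - {label: Poor, lower: 6.5, upper: 8.5, lower_closed: false, upper_closed: true}
      - {label: Very poor, lower: 8.5, upper: .inf, lower_closed: false, upper_closed: false}
  ept:
    direction: higher_is_better
    classes:
      - {label: Excellent, lower: 28.0, upper: .inf, lower_closed: false, upper_closed: false}
      - {label: Good, lower: 20.0, upper: 28.0, lower_closed: false, upper_closed: true}
      - {label: Fair, lower: 14.0, upper: 20.0, lower_closed: false, upper_closed: true}
      - {label: Poor, lower: 6.0, upper: 14.0, lower_closed: false, upper_closed: true}
      - {label: Very poor, lower: 0.0, upper: 6.0, lower_closed: true, upper_closed: true}
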