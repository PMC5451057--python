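# Simulation scenario grid for the type-I-error and power study.
#
# Scenario 0 is the null (no causal variants).  Scenarios 1-12 set all causal
# effects positive; 13-24 repeat the same causal fractions / effect-size
# constants with an 80/20 positive/negative split, 25-36 with a 50/50 split.
# causal_fraction is relative to the rare (MAF <= rare_threshold) SNVs of a
# gene; the effect of a causal variant is c * |log10(MAF)|.
defaults:
  rare_threshold: 0.03
  error_dist: normal
  trait: quantitative
  n: 1000
  m: 10000
scenarios:
  - {id: 0, causal_fraction: 0.0, c: 0.0, positive_fraction: 1.0, m: 10000000}
  - {id: 1, causal_fraction: 0.05, c: 0.6, positive_fraction: 1.0}
  - {id: 2, causal_fraction: 0.05, c: 0.3, positive_fraction: 1.0}
  - {id: 3, causal_fraction: 0.05, c: 0.2, positive_fraction: 1.0}
  - {id: 4, causal_fraction: 0.10, c: 0.6, positive_fraction: 1.0}
  - {id: 5, causal_fraction: 0.10, c: 0.3, positive_fraction: 1.0}
  - {id: 6, causal_fraction: 0.10, c: 0.2, positive_fraction: 1.0}
  - {id: 7, causal_fraction: 0.20, c: 0.6, positive_fraction: 1.0}
  - {id: 8, causal_fraction: 0.20, c: 0.3, positive_fraction: 1.0}
  - {id: 9, causal_fraction: 0.20, c: 0.2, positive_fraction: 1.0}
  - {id: 10, causal_fraction: 0.50, c: 0.6, positive_fraction: 1.0}
  - {id: 11, causal_fraction: 0.50, c: 0.3, positive_fraction: 1.0}
  - {id: 12, causal_fraction: 0.50, c: 0.2, positive_fraction: 1.0}
  - {id: 13, causal_fraction: 0.05, c: 0.6, positive_fraction: 0.8}
  - {id: 14, causal_fraction: 0.05, c: 0.3, positive_fraction: 0.8}
  - {id: 15, causal_fraction: 0.05, c: 0.2, positive_fraction: 0.8}
  - {id: 16, causal_fraction: 0.10, c: 0.6, positive_fraction: 0.8}
  - {id: 17, causal_fraction: 0.10, c: 0.3, positive_fraction: 0.8}
  - {id: 18, causal_fraction: 0.10, c: 0.2, positive_fraction: 0.8}
  - {id: 19, causal_fraction: 0.20, c: 0.6, positive_fraction: 0.8}
  - {id: 20, causal_fraction: 0.20, c: 0.3, positive_fraction: 0.8}
  - {id: 21, causal_fraction: 0.20, c: 0.2, positive_fraction: 0.8}
  - {id: 22, causal_fraction: 0.50, c: 0.6, positive_fraction: 0.8}
  - {id: 23, causal_fraction: 0.50, c: 0.3, positive_fraction: 0.8}
  - {id: 24, causal_fraction: 0.50, c: 0.2, positive_fraction: 0.8}
  - {id: 25, causal_fraction: 0.05, c: 0.6, positive_fraction: 0.5}
  - {id: 26, causal_fraction: 0.05, c: 0.3, positive_fraction: 0.5}
  - {id: 27, causal_fraction: 0.05, c: 0.2, positive_fraction: 0.5}
  - {id: 28, causal_fraction: 0.10, c: 0.6, positive_fraction: 0.5}
  - {id: 29, causal_fraction: 0.10, c: 0.3, positive_fraction: 0.5}
  - {id: 30, causal_fraction: 0.10, c: 0.2, positive_fraction: 0.5}
  - {id: 31, causal_fraction: 0.20, c: 0.6, positive_fraction: 0.5}
  - {id: 32, causal_fraction: 0.20, c: 0.3, positive_fraction: 0.5}
  - {id: 33, causal_fraction: 0.20, c: 0.2, positive_fraction: 0.5}
  - {id: 34, causal_fraction: 0.50, c: 0.6, positive_fraction: 0.5}
  - {id: 35, causal_fraction: 0.50, c: 0.3, positive_fraction: 0.5}
  - {id: 36, causal_fraction: 0.50, c: 0.2, positive_fraction: 0.5}
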