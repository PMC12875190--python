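# A small simulation grid: type I error and power of three method
# compositions under Cauchy noise, next to the F-test baseline.
# Run:  robustpalmrt simulate examples/study.yaml --out study.tsv
scenarios:
  - {n: 100, p: 6, error_law: cauchy, beta: 0.0,  B: 199, n_reps: 200, seed: 1, method: huber-huber}
  - {n: 100, p: 6, error_law: cauchy, beta: 0.0,  B: 199, n_reps: 200, seed: 1, method: ols-l2}
  - {n: 100, p: 6, error_law: cauchy, beta: 0.12, B: 199, n_reps: 200, seed: 2, method: huber-huber}
  - {n: 100, p: 6, error_law: cauchy, beta: 0.12, B: 199, n_reps: 200, seed: 2, method: ols-huber}
  - {n: 100, p: 6, error_law: cauchy, beta: 0.12, B: 199, n_reps: 200, seed: 2, method: ols-l2}
  - {n: 100, p: 6, error_law: cauchy, beta: 0.12, n_reps: 200, seed: 2, method: ftest}
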