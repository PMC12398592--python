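{
 "description": "Published STAT5 dimerisation reference: maximum-likelihood kinetic parameters and per-observable noise standard deviations.",
 "parameters": {
  "Epo_degradation_BaF3": 0.02698251405788074,
  "k_exp_hetero": 1.0006797375934156e-05,
  "k_exp_homo": 0.006170228082118995,
  "k_imp_hetero": 0.01636791842795611,
  "k_imp_homo": 97749.37944748683,
  "k_phos": 15766.507001421236
 },
 "sigma": {
  "pSTAT5A_rel": 3.8526119819951585,
  "pSTAT5B_rel": 6.591478183698705,
  "rSTAT5A_rel": 3.1527127564852666
 },
 "nll": 138.22
}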