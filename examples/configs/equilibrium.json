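{
  "grid": {"n": 16, "L": 8.0},
  "tau": 1.0,
  "activation": {"beta": 2.0, "u_star": 0.5},
  "kernel": {"family": "gaussian", "width": 1.0, "normalization": 1.0},
  "noise": {"family": "white", "T": 1.0},
  "simulate": {"dt": 0.002, "n_steps": 500000, "burn_in": 2000, "seed": 1},
  "tasks": ["epr-analytic", "check-equilibrium", "epr-path"]
}
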