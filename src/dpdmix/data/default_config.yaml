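composition:
  n1: 900
  n2: 900
  n_head1: 3
  n_tail1: 9
  n_head2: 3
  n_tail2: 9
  n_water: 59400
  box_lengths:
  - 30.0
  - 30.0
  - 30.0
  density: 3.0
interaction:
  a:
    H1-H1: 25.0
    H1-T1: 100.0
    H1-H2: 25.0
    H1-T2: 100.0
    H1-W: 25.0
    T1-T1: 25.0
    T1-H2: 100.0
    T1-T2: 100.0
    T1-W: 100.0
    H2-H2: 25.0
    H2-T2: 100.0
    H2-W: 25.0
    T2-T2: 25.0
    T2-W: 100.0
    W-W: 25.0
  gamma: 4.5
  sigma: 3.0
  rc: 1.0
  kBT: 1.0
bonded:
  ks: 120.0
  rs: 0.7
  k_theta: 6.0
  theta0: 3.141592653589793
units:
  rc_nm: 0.5
  tau_ns: 1.88
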