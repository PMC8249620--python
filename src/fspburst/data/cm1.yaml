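# Combinatorial model CM1: published fitted parameters (rates in s^-1,
# transcription in molecules s^-1).  IL-1beta: NF-kB enhances G1->G2;
# TNF-alpha: NF-kB enhances G0->G1.
name: CM1
signal:
  r1: 9.01e-04
  r2: 3.05e-04
genes:
  il1b:
    topology: 3S-act12
    k01: 3.89e-02
    k10: 7.62e-03
    k12: 3.93e-05
    k21: 8.37e-03
    b: 9.60e-03
    alpha0: 1.09e-04
    alpha1: 1.64e-05
    alpha2: 9.99e-01
    delta: 5.67e-05
    inhibitors:
      mg132:
        b: 2.83e-03
      u0126:
        k01: 2.22e-03
  tnfa:
    topology: 3S-act01
    k01: 1.21e-04
    k10: 4.67e-02
    k12: 8.19e-03
    k21: 3.98e-03
    b: 2.27e-02
    alpha0: 3.61e-05
    alpha1: 6.24e-01
    alpha2: 5.39e-01
    delta: 2.29e-04
    inhibitors:
      mg132:
        b: 7.80e-03
      u0126:
        k01: 1.00e-04
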