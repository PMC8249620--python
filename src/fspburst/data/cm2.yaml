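# Combinatorial model CM2: published fitted parameters (rates in s^-1,
# transcription in molecules s^-1).  IL-1beta: NF-kB suppresses G1->G0;
# TNF-alpha: NF-kB enhances G0->G1.
name: CM2
signal:
  r1: 1.03e-03
  r2: 4.39e-04
genes:
  il1b:
    topology: 3S-rep10
    k01: 4.77e-03
    k10: 7.66e-02
    k12: 5.50e-04
    k21: 8.79e-03
    b: 6.60e+00
    alpha0: 5.29e-05
    alpha1: 1.00e-06
    alpha2: 1.00e+00
    delta: 5.27e-05
    inhibitors:
      mg132:
        b: 6.80e-01
      u0126:
        k01: 2.22e-03
  tnfa:
    topology: 3S-act01
    k01: 1.17e-04
    k10: 5.48e-02
    k12: 9.41e-03
    k21: 4.03e-03
    b: 2.09e-02
    alpha0: 2.60e-05
    alpha1: 7.07e-01
    alpha2: 5.41e-01
    delta: 2.16e-04
    inhibitors:
      mg132:
        b: 7.18e-03
      u0126:
        k01: 1.00e-04
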