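{
  "kind": "lda",
  "description": "Reference seven-descriptor linear mt-QSAR discriminant for ERK-1/2 inhibition over Box-Jenkins deviation descriptors (literature model bundled as a worked example; fitted on 3585 condition-annotated training records).",
  "intercept": 1.653,
  "coefficients": {
    "D[Tnsq5(CH)N2]_me": -0.080,
    "D[Tnsq3(CH)MN]_bt": -1.842,
    "D[Tssq11(CH)MN]_me": 18.180,
    "D[Tssq5(POL)MX]_me": -0.027,
    "D[Tnsq1(PSA)GM]_me": 0.005,
    "D[Tnsq13(VDW)N2]_bt": 0.003,
    "D[Tssq2(HYD)N1]_me": -0.111
  },
  "stats": {
    "wilks_lambda": 0.397,
    "canonical_R": 0.776,
    "chi_square": 3302.20,
    "mahalanobis_D2": 6.54,
    "fisher_F": 774.498,
    "p_value": 1e-16,
    "n": 3585,
    "p": 7
  }
}
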