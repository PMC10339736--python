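# Functional registry, version 1.
#
# Class (family) and empirical-parameter counts follow the benchmark-set
# definitions of the assessed functionals; the numeric mixing/scaling
# parameters (alpha_x, c_os, c_ss, omega) are taken from the cited original
# functional papers.  Entries flagged `approximate: true` carry best-effort
# transcriptions that should be cross-checked against the citation before
# production use with a real SCF backend; they do not affect any shipped
# test, which always passes scales explicitly.
#
# c_os / c_ss are the opposite-/same-spin weights on the second-order
# correction (a global single-parameter double hybrid has c_os = c_ss =
# alpha_C; SOS variants have c_ss = 0).  omega is the range-separation
# parameter in inverse bohr where applicable.

registry_version: 1
functionals:
  - name: SCS-RS-PBE-P86
    aliases: []
    exchange: PBE
    correlation: P86
    family: RS_DH
    ansatz: adc2
    n_empirical_params: 4
    alpha_x: 0.62
    c_os: 1.00
    c_ss: 0.60
    omega: 0.45
    citation: "Mester & Kallay, J. Chem. Theory Comput. 17, 4211 (2021)"
    approximate: true
  - name: SOS-RS-PBE-P86
    aliases: []
    exchange: PBE
    correlation: P86
    family: RS_DH
    ansatz: adc2
    n_empirical_params: 3
    alpha_x: 0.62
    c_os: 1.20
    c_ss: 0.00
    omega: 0.45
    citation: "Mester & Kallay, J. Chem. Theory Comput. 17, 4211 (2021)"
    approximate: true
  - name: "SCS-ωPBEPP86"
    aliases: [SCS-wPBEPP86, SCS-omegaPBEPP86]
    exchange: PBE
    correlation: P86
    family: LC_DH
    ansatz: cisd
    n_empirical_params: 7
    alpha_x: 0.69
    c_os: 0.58
    c_ss: 0.48
    omega: 0.30
    citation: "Casanova-Paez & Goerigk, J. Chem. Theory Comput. 17, 5165 (2021)"
    approximate: true
  - name: "SOS-ωPBEPP86"
    aliases: [SOS-wPBEPP86, SOS-omegaPBEPP86]
    exchange: PBE
    correlation: P86
    family: LC_DH
    ansatz: cisd
    n_empirical_params: 5
    alpha_x: 0.69
    c_os: 0.90
    c_ss: 0.00
    omega: 0.30
    citation: "Casanova-Paez & Goerigk, J. Chem. Theory Comput. 17, 5165 (2021)"
    approximate: true
  - name: DSD-PBEP86
    aliases: []
    exchange: PBE
    correlation: P86
    family: global_DH
    ansatz: adc2
    n_empirical_params: 4
    alpha_x: 0.70
    c_os: 0.53
    c_ss: 0.25
    omega: null
    citation: "Kozuch & Martin, Phys. Chem. Chem. Phys. 13, 20104 (2011)"
    approximate: true
  - name: PBE0-2
    aliases: []
    exchange: PBE
    correlation: PBE
    family: global_DH
    ansatz: adc2
    n_empirical_params: 2
    alpha_x: 0.793701  # 2^(-1/3)
    c_os: 0.50
    c_ss: 0.50
    omega: null
    citation: "Chai & Mao, Chem. Phys. Lett. 538, 121 (2012)"
    approximate: false
  - name: SOS-PBE0-2
    aliases: []
    exchange: PBE
    correlation: PBE
    family: global_DH
    ansatz: adc2
    n_empirical_params: 3
    alpha_x: 0.793701
    c_os: 0.60
    c_ss: 0.00
    omega: null
    citation: "Alipour, Theor. Chem. Acc. 134, 87 (2015)"
    approximate: true
  - name: PBE-QIDH
    aliases: []
    exchange: PBE
    correlation: PBE
    family: global_DH
    ansatz: adc2
    n_empirical_params: 2
    alpha_x: 0.693361  # 3^(-1/3)
    c_os: 0.333333
    c_ss: 0.333333
    omega: null
    citation: "Bremond, Sancho-Garcia, Perez-Jimenez & Adamo, J. Chem. Phys. 141, 031101 (2014)"
    approximate: false
  - name: B2GPPLYP
    aliases: [B2GP-PLYP]
    exchange: B88
    correlation: LYP
    family: global_DH
    ansatz: adc2
    n_empirical_params: 2
    alpha_x: 0.65
    c_os: 0.36
    c_ss: 0.36
    omega: null
    citation: "Karton, Tarnopolsky, Lamere, Schatz & Martin, J. Phys. Chem. A 112, 12868 (2008)"
    approximate: false
  - name: "ωB97X-D"
    aliases: [wB97X-D, omegaB97X-D]
    exchange: B97
    correlation: B97
    family: lc_hybrid
    ansatz: none
    n_empirical_params: 18
    alpha_x: 0.222036  # short-range exact-exchange fraction
    c_os: 0.0
    c_ss: 0.0
    omega: 0.20
    citation: "Chai & Head-Gordon, Phys. Chem. Chem. Phys. 10, 6615 (2008)"
    approximate: false
  - name: CAM-B3LYP
    aliases: []
    exchange: B88
    correlation: LYP
    family: lc_hybrid
    ansatz: none
    n_empirical_params: 3
    alpha_x: 0.19  # short-range fraction; long-range reaches 0.65
    c_os: 0.0
    c_ss: 0.0
    omega: 0.33
    citation: "Yanai, Tew & Handy, Chem. Phys. Lett. 393, 51 (2004)"
    approximate: false
  - name: PBE0
    aliases: []
    exchange: PBE
    correlation: PBE
    family: global_hybrid
    ansatz: none
    n_empirical_params: 1
    alpha_x: 0.25
    c_os: 0.0
    c_ss: 0.0
    omega: null
    citation: "Adamo & Barone, J. Chem. Phys. 110, 6158 (1999)"
    approximate: false
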