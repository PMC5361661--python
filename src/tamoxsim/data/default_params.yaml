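checksum: 6104a13ed2300a66
cv_clearance: 0.37
cv_volume: 0.0
network:
  CLe_4OH: 751.270785113626
  CLe_END: 140.27025251437385
  CLe_NDM: 53.66152569210215
  CLe_TAM: 38.05699609625396
  CLf_4OH_END: 735.4955401207002
  CLf_NDM_END: 10.055696338360347
  CLf_TAM_4OH: 1.4517560230880473
  CLf_TAM_NDM: 128.4861674016369
  F_END: 0.8391126516794216
  F_TAM: 1.0
  V_4OH: 1500.0000000000005
  V_END: 503.97498262573674
  V_NDM: 1350.0
  V_TAM: 1199.9999999999995
  ka_END: 23.996441480623858
  ka_TAM: 4.0
provenance:
  anchors_failing_gate: 10
  calibration_seed: 1234
  release_gate_n: 1000
schema_version: 1
theta_IM: 0.6951458113030016
theta_PM: 0.07161873096489642
version: calibrated-v1
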