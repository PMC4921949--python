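{
  "HCM": ["HCM", "NOONAN_RAS", "FABRY"],
  "DCM": ["HCM", "DCM", "ARVD", "DMD_BECKER"],
  "UNSPECIFIED_CM": ["HCM", "DCM", "ARVD", "NOONAN_RAS", "FABRY", "DMD_BECKER"],
  "ARVD": ["DCM", "ARVD", "BRGDA", "CPVT", "UNSPECIFIED_ARRHYTHMIA"],
  "UNSPECIFIED_ARRHYTHMIA": ["HCM", "DCM", "ARVD", "LQTS", "SQTS", "BRGDA", "CPVT", "UNSPECIFIED_ARRHYTHMIA"]
}
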