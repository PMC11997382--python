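{
  "version": 1,
  "units": "cm^-1 per (mol/L)",
  "note": "Molar extinction coefficients of oxy- and deoxyhemoglobin, compiled from standard published whole-blood spectra and interpolated to the instrument wavelengths. The same table drives both the forward simulator and the inverse concentration solve, so the pipeline round-trips exactly; table choice affects absolute scaling only.",
  "wavelengths_nm": [703.0, 808.0, 850.0],
  "hbo": {"703.0": 298.0, "808.0": 844.0, "850.0": 1058.0},
  "hbr": {"703.0": 1740.0, "808.0": 724.0, "850.0": 691.3}
}
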