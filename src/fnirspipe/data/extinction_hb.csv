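# Molar extinction coefficients of human hemoglobin, cm^-1 / (mol/L),
# base-10 (decadic) convention, interpolated from the standard compiled
# tabulations of Gratzer and Kollias as distributed by S. Prahl (Oregon
# Medical Laser Center, 1998).  User-overridable: pass any file with the
# same columns to ExtinctionTable.from_csv.
wavelength_nm,hbo,hbr
660,319.6,3226.56
690,276.0,2051.96
750,518.0,1405.24
808,856.0,717.08
830,974.0,693.04
850,1058.0,691.32
880,1170.0,742.0
940,1214.0,693.44
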