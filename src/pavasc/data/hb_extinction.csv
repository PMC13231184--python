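# Molar extinction coefficients of human oxy- and deoxy-hemoglobin (cm^-1/M),
# adapted from the tabulated compilation by S. Prahl, Oregon Medical Laser
# Center (https://omlc.org/spectra/hemoglobin/), subsampled to a coarse grid;
# values between grid points are linearly interpolated.
wavelength_nm,eps_hbo2,eps_hb
500,20932.8,20862.0
525,33209.2,29412.8
532,44480.0,40584.0
550,43016.0,52276.0
575,59292.0,49094.0
600,3200.0,14677.2
625,740.8,5776.8
650,368.0,3750.1
675,282.0,2795.1
700,290.0,1794.3
725,400.0,1263.0
750,518.0,1405.2
760,586.0,1548.5
775,700.0,1130.0
800,816.0,761.7
825,940.0,710.0
850,1058.0,691.3
875,1138.0,726.4
900,1198.0,761.8
925,1220.0,795.0
950,1204.0,828.9
975,1166.0,860.0
1000,1096.0,887.2
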