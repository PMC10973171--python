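# Builtin photometric and mass constants for ribonucleoside residues.
#
# lambda_max  : wavelength of the absorption peak, nm (pH 7.4 phosphate buffer)
# eps_max     : molar absorption coefficient at lambda_max, M^-1 cm^-1
# eps_260     : molar absorption coefficient at 260 nm, M^-1 cm^-1
# residue_mass: average mass of the internal monophosphate residue
#               (nucleoside 5'-monophosphate free acid minus one water), g/mol
#
# Standard-nucleoside coefficients are the classical neutral-pH literature
# values; modified-nucleoside coefficients are set so that the measured
# relative differences against their canonical references (bathochromic
# lambda_max shifts and hypochromic eps reductions) are reproduced exactly.
# Masses are average (not monoisotopic) masses under the free-acid convention.

nucleosides:
  A:
    name: adenosine
    lambda_max: 259.5
    eps_max: 15400.0
    eps_260: 15340.0
    residue_mass: 329.206
    provenance: classical neutral-pH literature value (adenosine)
  C:
    name: cytidine
    lambda_max: 271.0
    eps_max: 9100.0
    eps_260: 7400.0
    residue_mass: 305.181
    provenance: classical neutral-pH literature value (cytidine)
  G:
    name: guanosine
    lambda_max: 252.5
    eps_max: 13700.0
    eps_260: 11800.0
    residue_mass: 345.205
    provenance: classical neutral-pH literature value (guanosine)
  U:
    name: uridine
    lambda_max: 262.0
    eps_max: 10100.0
    eps_260: 10000.0
    residue_mass: 306.166
    provenance: classical neutral-pH literature value (uridine)
  T:
    name: thymidine
    lambda_max: 267.0
    eps_max: 9797.0
    eps_260: 8860.0
    residue_mass: 304.193
    provenance: >
      uridine values scaled by the historical 5-methyl effect
      (-3% at lambda_max, -11.4% at 260 nm, +5 nm shift); deoxyribose mass
  Y:
    name: pseudouridine
    lambda_max: 263.0
    eps_max: 7900.0
    eps_260: 7798.0
    residue_mass: 306.166
    provenance: >
      neutral-pH pseudouridine peak; eps_260 consistent with the measured
      -22.8% reduction from pseudouridine to N1-methylpseudouridine
  m1Y:
    name: N1-methylpseudouridine
    lambda_max: 272.0
    eps_max: 7979.0
    eps_260: 6020.0
    residue_mass: 320.192
    provenance: >
      measured relative to uridine (-21% at lambda_max, -39.8% at 260 nm)
      and pseudouridine (+9 nm shift)
  m5C:
    name: 5-methylcytidine
    lambda_max: 278.0
    eps_max: 8300.0
    eps_260: 5860.0
    residue_mass: 319.207
    provenance: >
      measured relative to cytidine (+7 nm shift, -20.8% at 260 nm)
  m7G:
    name: 7-methylguanosine
    lambda_max: 258.0
    eps_max: 11600.0
    eps_260: 11400.0
    residue_mass: 359.232
    provenance: neutral-pH literature value (7-methylguanosine, cap chromophore)

caps:
  none:
    eps_260_add: 0.0
    mass_add: 0.0
  cap0:
    # m7GpppN: 7-methylguanosine (297.268) plus a 5'-5' triphosphate bridge
    # (triphosphoric acid 257.955 minus two condensation waters), relative to
    # a 5'-hydroxyl end.
    eps_260_add: 11400.0
    mass_add: 519.193
  cap1:
    # cap0 plus a 2'-O-methyl on the first transcribed nucleotide; the methyl
    # adds mass but no chromophore.
    eps_260_add: 11400.0
    mass_add: 533.220
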