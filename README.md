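# mrnaquant

UV-spectrophotometric quantification of nucleoside-modified mRNA.

Therapeutic mRNAs replace uridine with N1-methylpseudouridine (m¹Ψ) — and
sometimes cytidine with 5-methylcytidine (m⁵C) — to dampen innate-immune
sensing. These modifications are hypochromic: m¹Ψ absorbs ~40% less UV light
at 260 nm than uridine, so a modified mRNA absorbs measurably less than its
unmodified isosequence. Quantifying such an mRNA from its A₂₆₀ with an
unmodified extinction coefficient (or the legacy 40 µg/mL-per-AU ssRNA rule)
under-estimates its concentration by roughly 5–15%, depending on how much
uridine the sequence carries. `mrnaquant` computes composition-aware molar
absorption coefficients and converts absorbance readings into concentrations
and amounts, for anyone doing mRNA synthesis or quality control.

## Model

For a hydrolyzed mRNA (hydrolysis removes folding-induced hypochromicity),
the molar absorption coefficient at 260 nm is additive over residues:

    MAC₂₆₀ = Σᵢ nᵢ · ε₂₆₀(i) + ε₂₆₀(cap)

where the sum runs over A, C, G, U and any modified residues, and a Cap0/Cap1
structure contributes the 7-methylguanosine chromophore once. The
Beer-Lambert law `A₂₆₀ = MAC₂₆₀ · l · c` then gives the stock concentration
from a single diluted reading, or — more robustly — from the slope of an
ordinary-least-squares fit of A₂₆₀ against 1/dilution over a serial-dilution
series. The predicted hypochromicity of a modification scheme is the ratio
MAC₂₆₀(modified)/MAC₂₆₀(unmodified); `100·(1 − ratio)` is the percent by
which a concentration is under-estimated when the unmodified coefficient is
applied.

The builtin constants table records λmax, εmax, ε₂₆₀ and the average residue
mass for A, C, G, U, T, Ψ (`Y`), m¹Ψ (`m1Y`), m⁵C (`m5C`) and m⁷G (`m7G`),
and reproduces the measured nucleoside-level differences exactly (e.g.
Δε₂₆₀ = −39.8% for U→m¹Ψ, −20.8% for C→m⁵C, bathochromic shifts of +9/+7 nm).
Any field can be overridden through a YAML config (`--registry`).

## Worked example

A Cap1 construct fully substituted with m¹Ψ:

```
$ mrnaquant calc --fasta demo.fa --mod U:m1Y --cap cap1
[
  {
    "id": "demo",
    "length": 51,
    "cap": "cap1",
    "scheme": "U:m1Y:1",
    "mac_260_per_M_cm": 538700.0,
    "mol_weight_g_per_mol": 17158.325,
    "mass_extinction_ug_per_mL_AU": 31.851355114163727,
    "composition": {"A": 13, "G": 15, "C": 9, "m1Y": 14},
    "hypochromicity_ratio": 0.9062615658961677,
    "underestimation_percent": 9.37384341038323
  }
]
```

The construct's molar absorption is 538,700 M⁻¹cm⁻¹ and one absorbance unit
corresponds to 31.85 µg/mL — the m¹Ψ substitution lowers absorption to 90.6%
of the unmodified value, so ignoring it would under-report the concentration
by 9.4%.

Quantifying the same construct from a serial-dilution series
(`dilution,a260` CSV, one row per replicate) with a 150 µL stock:

```
$ mrnaquant quantify --fasta demo.fa --mod U:m1Y --cap cap1 \
      --series series.csv --volume 150
[
  {
    "id": "demo",
    "molar_concentration_nM": 16970.32308052397,
    "mass_concentration_ng_per_uL": 291.1823187706314,
    ...
    "total_amount_umol": 0.0025455484620785958,
    "total_amount_ug": 43.67734781559471,
    "fit": {"slope_AU": 9.14, "intercept_AU": 0.0008, "pearson_r": 0.99999996,
            "intercept_warning": false},
    "legacy_40ug_per_mL_estimate_ng_per_uL": 365.67652173913046
  }
]
```

The stock is 16.97 µM (291 ng/µL, 43.7 µg in total); the near-zero fitted
intercept and r ≈ 1 indicate clean handling, and the legacy 40 µg/mL rule
would have reported 366 ng/µL — a 26% overshoot for this short, m¹Ψ-rich
construct.

The same operations are available from Python (`mrnaquant.compute_mac`,
`fit_dilution_series`, `fit_beer_lambert`, ...), and
`mrnaquant.fixtures` generates seeded synthetic sequences and dilution
series with known ground truth.

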