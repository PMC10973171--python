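# Methods

## Model and assumptions

`mrnaquant` treats a hydrolyzed mRNA as a mixture of mononucleotides, so its
molar absorption coefficient at 260 nm is the composition-weighted sum of
per-residue coefficients plus a single cap contribution:

    MAC260 = sum_i n_i * eps260(i) + eps260_add(cap)

The additivity assumption holds only after hydrolysis: folding-induced
hypochromicity in intact RNA is buffer-, sequence- and
concentration-dependent and is not modelled. The calculator therefore
targets hydrolyzed samples; dilution introduced by a hydrolysis protocol is
an explicit user input (the `dilution` field), never corrected internally.
No temperature, pH, or ionic-strength dependence is modelled — the constants
table is a single-condition (neutral-pH dilute aqueous buffer) table.

The per-residue coefficients are nucleoside measurements applied to
mononucleotide samples; the nucleoside-vs-monophosphate difference in eps260
is below the accuracy the tool targets and is deliberately ignored.

## The constants table

The builtin table (`src/mrnaquant/data/nucleosides.yaml`) stores, per
residue code: `lambda_max` (nm), `eps_max` and `eps_260` (M^-1 cm^-1), and
`residue_mass` (g/mol, average mass of the internal monophosphate residue).
Standard-nucleoside coefficients are the classical neutral-pH literature
values; the modified-nucleoside coefficients are anchored to them so that
the measured relative differences are reproduced exactly:

| pair     | delta lambda_max | delta eps_max | delta eps_260 |
|----------|------------------|---------------|---------------|
| C → m5C  | +7 nm            | —             | −20.8%        |
| Y → m1Y  | +9 nm            | —             | −22.8%        |
| U → m1Y  | +10 nm           | −21%          | −39.8%        |
| U → T    | +5 nm            | −3%           | −11.4%        |

Anchoring to relative differences is the robust choice: the ratios are what
propagate into construct-level hypochromicity, while the absolute scale
cancels out of every ratio and enters concentrations only through the
standard-nucleoside values, which are well established. Each entry carries a
`provenance` comment. Every field is user-overridable per code through a
YAML config with the same schema; overrides merge per field, so a config
can change a single coefficient.

ASCII codes (`Y`, `m1Y`, `m5C`, `m7G`) are canonical because Unicode Greek
letters survive neither FASTA files nor shells reliably; Unicode spellings
are accepted on input and normalized.

## Molecular weight

Average (not monoisotopic) masses, free-acid convention:

    MW = sum_i n_i * residue_mass(i) + H2O + end adjustment

with 5' end adjustments: monophosphate +0 (the baseline; a single A residue
gives AMP free acid, 347.22 g/mol), hydroxyl −HPO3 (79.98), triphosphate
+2·HPO3. Triphosphate is the default because uncapped in vitro transcription
products carry one. A capped construct instead takes the cap's mass on a
hydroxyl baseline: Cap0 adds 7-methylguanosine plus a 5'-5' triphosphate
bridge (519.19 g/mol); Cap1 adds one further 2'-O-methyl (+14.03 g/mol,
no chromophore — its eps260 contribution equals Cap0's). The first
transcribed nucleotide is part of the sequence and never double-counted.

## Hypochromicity and under-estimation

A modification scheme is a set of canonical→modified substitutions with
fractions in [0, 1]. Applying a scheme keeps real-valued residue counts so
MAC260 is exactly linear in every fraction; integer rounding (half-up) is
applied only to discrete composition reports. The hypochromicity ratio is
MAC260(modified)/MAC260(unmodified) with identical caps on both sides, and
the under-estimation percent is 100·(1 − ratio). For a homopolymer the
ratio collapses to the nucleoside-level coefficient ratio; for typical mRNA
uridine fractions (0.15–0.35) full m1Y substitution yields roughly 5–13%
under-estimation, growing with uridine content.

## Quantification

Single measurement: `c_stock = A260 / (MAC260 · l) · dilution`, reported in
nM; mass concentration in ng/µL via the molecular weight (1 nM · 1 g/mol =
10^-6 ng/µL); totals in µmol and µg from the stock volume in µL. The legacy
40 µg/mL-per-AU ssRNA estimate is computed alongside for comparison only.

Serial-dilution series: ordinary least squares of the per-dilution mean
A260 against 1/dilution, **with** an intercept. The slope estimates the
undiluted stock absorbance, which averages out per-handling pipetting
error; the intercept is a free diagnostic — a fitted intercept beyond
±0.005 AU (about the reproducibility of a good blank) raises a
blank/baseline warning rather than silently biasing the estimate. A
regression through the origin would hide exactly that failure mode, which
is the workflow's reason to exist. Replicates are averaged per point
(unweighted) by default; `pooled=True` regresses every replicate, which
changes nothing for balanced designs but weights points by replicate count
otherwise. A single-point series falls back to the direct Beer-Lambert
calculation.

Calibration (`fit_beer_lambert`) is the inverse direction: absorbance
regressed on known molar concentration, slope/path-length as the
coefficient estimate, Pearson r reported; readings above 1.0 AU draw a
linear-range warning.

Degenerate inputs: empty sequences have MAC260 = 0 and a defined molecular
weight of 0, but any ratio or concentration built on them raises; duplicate
dilution factors and constant calibration designs raise degenerate-design
errors rather than returning an unstable fit.

User-facing text output rounds to 4 significant figures; JSON output keeps
full precision.

## Synthetic data

`fixtures.random_sequence` draws i.i.d. residues at specified base
fractions; `fixtures.simulate_series` produces replicate readings
`MAC260 · l · c / dilution · (1 + N(0, cv))`. Noise is multiplicative
because photometric replicate error scales with signal; negative draws
(possible only at unrealistically large CV) are clipped to zero. Both are
pure functions of their spec, and the seed is embedded in generated record
ids. Default simulation conditions: a 6-point two-fold dilution ladder
(1–32×), 3 replicates, 1% CV — a realistic benchtop spectrophotometer
scenario. The generator emulates neither instrument nonlinearity above
1 AU, nor baseline drift, nor hydrolysis kinetics, nor folding effects; a
passing recovery test therefore demonstrates correctness of the estimator,
not robustness to those real-world artifacts.

Test problem sizes — 1,000 random sequences (lengths 1–2,000) for the
additivity oracle, 200 seeded simulations for dilution-series recovery,
500 for calibration bias — were chosen to make Monte-Carlo conclusions
stable at the tolerances asserted.

## Known limitations

- Valid only for hydrolyzed (or otherwise unfolded) RNA; intact folded mRNA
  will read low against these coefficients.
- The modified-nucleoside coefficient set covers Y, m1Y, m5C, T and the cap;
  other modifications (m6A, 2'-O-methyl internal residues, ...) must be
  supplied via a registry config.
- Masses assume the free-acid convention; vendor calculators using salt
  forms will differ by counterion masses.
- Partial-substitution predictions assume random incorporation; position
  effects on absorption are not modelled (and vanish after hydrolysis).
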