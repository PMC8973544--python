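# Methods

## Risk model

The package treats excess lifetime cancer risk as strictly proportional
to cumulative intake (linear low-dose extrapolation, no threshold).
Under that assumption a lifetime acceptable daily intake (ADI) at a
stated excess cancer risk (ECR) is equivalent to a total budget, the
maximum lifetime intake MLI = ADI × lifetime days, and any
(duration, risk) pair maps to a daily limit by

    ADI_adj = MLI / t_Ex × ECR_adj / ECR_def.

Assumptions worth making explicit:

- **Linearity.** Redistribution over time and rescaling of risk are
  both linear. Rare short peak exposures (spills) are assumed not to
  perturb the lifetime budget disproportionately.
- **The anchor is generic, not compound-specific.** The default point
  of departure (1.5 μg/day at 1:100,000, single substance) is a
  TTC-class value for uncharacterized genotoxic carcinogens; it is not
  derived from any one drug's potency. Compound-specific limits from
  TD50 data are out of scope.
- **Lifetime convention.** 70 years × 365 days = 25,550 days; leap days
  ignored. The occupational scenario is an exact product
  t_Ex = working_years × exposure_days_per_year with no part-time
  discounting (callers who need it can pass raw day counts).

### Parameters and presets

| parameter | default | unit | meaning |
| --- | --- | --- | --- |
| `adi_lifetime` | 1.5 (presets: 5 multiple-substances, 0.15 TTC) | μg/day | lifetime anchor intake |
| `excess_risk` | 1e-5 (TTC preset: 1e-6) | fraction | risk the anchor corresponds to (ECR_def) |
| `lifetime_days` | 25,550 | days | lifetime exposure duration |
| `working_years` × `exposure_days_per_year` | 40 × 240 | — | occupational scenario (t_Ex = 9600 d) |
| `ecr_adj` | 1e-5 (presets: 4e-5 TRGS acceptance, 4e-3 TRGS tolerance) | fraction | policy risk level |

The staged less-than-lifetime intake of 120 μg/day for exposures under
one month is carried as a documented constant
(`STAGED_TTC_LESS_THAN_1_MONTH_UG_PER_DAY`) only; it comes from a
different staging table and is *not* reproducible from the MLI
redistribution, so the package never computes with it.

### Reporting policy

Published occupational limits are round numbers. Exact values are
always retained; the reported form rounds to **two significant figures,
half-away-from-zero** (Decimal-based, so 12.5 → 13 rather than banker's
12). This single rule reproduces the adopted limits 4, 16 and 1600
μg/day from their exact counterparts 3.9921875, 15.96875 and 1596.875.
Adjustments always start from exact values and round once at the end;
re-adjusting an already-rounded limit would compound rounding error.

## Dermal exposure and the surface threshold

The uptake model is deliberately worst-case: the daily dermal intake
equals the entire drug load on a surface patch the size of both palms,
with complete systemic uptake.

| parameter | default | unit | meaning |
| --- | --- | --- | --- |
| `sa_ex` | 200 | cm² | exposed skin area (both palms) |
| `af_bio` | 1.0 | fraction | bioavailability adjustment (1 = 100 % uptake) |

Values of `af_bio` below 1 are permitted but emit a warning, since they
abandon the worst-case position. No skin-permeation kinetics, glove
penetration, or inhalation/oral reconstruction is modelled (those
routes are argued negligible under modern handling practice).

The safe-condition rule is DDI/ADI ≤ 1 with the boundary **inclusive**;
the acceptable surface contamination level inverts it, ASCL = ADI /
SA_Ex. The ASCL is conventionally derived from the *reported* ADI
(4000 ng/day → 20 ng/cm²) rather than the exact 3992.1875 ng/day — the
threshold is a communicated, round policy number — but `compute_ascl`
accepts any positive intake so the exact variant is one call away.
With `af_bio = 1` the DDI verdict and the sc ≤ ASCL comparison are dual;
with `af_bio < 1` the DDI route is strictly more permissive.

DDI aggregation across multiple surfaces touched in one shift has no
published rule; the package exposes per-surface DDI only and leaves any
summing to the caller.

## Structural screen

TTC applicability is decided per molecule from four mechanisms, in
order: an optional name-based deny list (empty by default), the
protein/biologic exclusion, the metal exclusion, and the structural
alert catalogue.

- **Biologics.** The primary mechanism is the explicit `is_biologic`
  flag — monoclonal antibodies have no meaningful SMILES. As a
  fallback, a parsed structure above 2000 Da without a flag is treated
  as biologic-like, with a warning.
- **Metals.** Any atom outside the organic set
  {H, B, C, N, O, F, Si, P, S, Cl, Br, I} flags the molecule. This
  covers the platinum and arsenic drugs without enumerating the
  periodic table; note it also flags salt counter-ions (Na⁺ etc.), so
  structures should be supplied as free acids/bases.
- **Alerts.** The catalogue (`data/alerts.yaml`) is data-driven and
  editable. The shipped patterns are minimal cohort-of-concern
  proxies: N-nitroso `[NX3][NX2]=[OX1]`; azoxy as the charged form
  `[#6][NX2]=[NX3+][OX1-]` plus its uncharged valence-tautomer
  spelling; aflatoxin-like as the fused furo[2,3-b]furan bicycle (the
  acetal carbon shared by two oxygen-bearing five-membered rings,
  matched with any-bond SMARTS so both the dihydro and unsaturated
  forms hit); polyhalogenated scaffold as a dibenzo-p-dioxin,
  dibenzofuran or biphenyl core gated on ≥ 4 halogen atoms. These flag
  classes for expert review; they are not a QSAR mutagenicity model,
  and stricter patterns can be swapped in via YAML.
- IARC group is pass-through metadata and never affects the verdict.

The bundled panel (`data/drug_panel.csv`, 29 records) contains common
antineoplastic drugs plus reference carcinogens (azoxymethane,
aflatoxin B1, TCDD, PCB 77) so every alert class has a positive
control. The nitrosourea SMARTS verdicts are cross-checked in the test
suite against an independent naive atom-neighbourhood walk.

## Survey handling

The bundled `data/surface_survey_review.csv` transcribes a published
review of wipe-sampling studies, one CSV row per printed table line
(27 rows across pharmacy, administration, patient-care and
operating-room areas). Units are normalized to ng/cm² via decimal
exponent shifts (`Decimal.scaleb`), which keeps power-of-ten unit
round-trips bit-exact for printed-decimal values — plain float
multiplication by 1e-3 does not.

Conventions:

- Rows printing a range of a summary statistic (e.g. a median range
  across sites) keep the range bounds with the summary `stat_kind`; no
  distribution is invented. Threshold comparison uses `value_high`,
  the conservative end.
- "ND"/"<LOD" parse as left-censored with value 0; "< x" keeps x with
  the censoring flag. Censored lows never enter maxima, which is what
  the assessment uses.
- Classification against an ASCL is boundary-inclusive (value = ASCL
  is "below"), mirroring DDI/ADI ≤ 1. Exceedances are labelled
  `exceeds_at_high` (range maxima) or `exceeds_at_summary`
  (mean/median/p75), since a summary-level exceedance is the stronger
  signal.
- Platinum-analyte rows are kept but excluded from verdict counts by
  default (metal compounds fall outside the TTC screen); pass
  `include_pt=True` to assess them.
- Malformed rows are rejected individually with row numbers, never by
  aborting the file.

## Synthetic campaigns

`simulate` generates wipe campaigns for testing the survey/dermal
pipeline without real data. Per facility area, samples are drawn
log-normal — the standard occupational-hygiene model, and consistent
with published ranges spanning five orders of magnitude — parameterized
by geometric median and geometric standard deviation (GSD), with
accidental spills as a point-mass mixture (each sample independently
replaced by a fixed spill magnitude with small probability).

Defaults emulate the reviewed studies: area medians 0.01–0.5 ng/cm²
(pharmacy hottest), GSD 3–4, 50–100 samples per area, spill
probability 1 % at 1000 ng/cm². A single seeded
`numpy.random.Generator` drives the whole campaign; identical seeds
reproduce campaigns exactly, and at n = 10,000 the sample geometric
median and GSD recover their inputs within 5 %.

What the generator does *not* emulate: spatial/temporal correlation
between samples, censoring at detection limits, cleaning dynamics, and
multi-analyte correlation. Passing tests on synthetic campaigns
therefore demonstrate correct plumbing and classification logic, not
validity of the log-normal assumption for any particular facility.

## Numerical choices and problem sizes

- All headline quantities are closed-form; the only stochastic
  component is the simulator. Test-suite simulations use n ≤ 10,000
  draws; the whole suite runs in a few seconds.
- Risk ratios are stored as fractions; the CLI parses both `1e-5` and
  ratio notation (`4:100.000`, European separators read as thousands
  marks).
- Equality-sensitive invariants (risk linearity, duration round-trip)
  are held to 1e-12 relative; they are pure float multiplications and
  divisions, so nothing looser is needed.

## Known limitations

- The TTC logic is a screening-level, deliberately conservative
  construct; it estimates an upper bound on acceptable exposure, not an
  actual risk for any specific drug.
- The bundled review table reflects a fixed literature snapshot;
  quantitative data exist only for surface contamination, so inhalation
  is handled by exclusion argument, not measurement.
- The screen's biologic fallback (MW > 2000 Da) is a heuristic; records
  for biologics should carry the explicit flag.
- No aggregation across simultaneously contaminated surfaces, no
  multi-drug additivity rule beyond choosing the multiple-substances
  anchor preset.
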