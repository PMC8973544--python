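# ttcrisk

Quantitative cancer-risk assessment for health workers occupationally
exposed to genotoxic (antineoplastic) drugs, built on the threshold of
toxicological concern (TTC) concept.

Pharmacists, nurses and hygienists in healthcare facilities handle
drugs that are mutagenic or carcinogenic by design. Hazard-based safety
guidance says "as low as reasonably possible" but gives no quantitative
criterion for when measured workplace contamination is actually of
concern. `ttcrisk` implements such a criterion: it converts a TTC-style
acceptable daily intake into occupational exposure limits, translates
them into a surface-contamination threshold that wipe-sampling
campaigns can be compared against, and screens drug molecules for the
structural classes to which the TTC logic may not be applied.

## The model

Linear low-dose extrapolation makes excess lifetime cancer risk
proportional to total lifetime intake. A lifetime acceptable daily
intake — by default the ICH M7 value of 1.5 μg/day at an excess risk of
1:100,000 over a 70-year lifetime (25,550 exposure days) — therefore
defines a **maximum lifetime intake**

```
MLI (μg) = ADI_lifetime × lifetime_days          = 1.5 × 25,550 = 38,325 μg
```

which can be redistributed over a shorter working life of t_Ex exposure
days and rescaled to a different acceptable excess cancer risk (ECR):

```
ADI     (μg/day) = MLI / t_Ex
ADI_adj (μg/day) = MLI / t_Ex × ECR_adj / ECR_def
```

Dermal contact with contaminated surfaces is the dominant exposure
route; the worst-case uptake model sets the **daily dermal intake** to
the drug load on a palm-sized patch of surface (SA_Ex = 200 cm², 100 %
bioavailability):

```
DDI (ng/day) = SA_Ex × SC / AF_Bio
```

Safe working conditions are assumed while DDI/ADI ≤ 1, which inverts
into an **acceptable surface contamination level**

```
ASCL (ng/cm²) = ADI (ng/day) / SA_Ex (cm²)
```

The TTC applies only to molecules resembling the databases it was
derived from: metal-containing drugs (platinum, arsenic), proteins and
monoclonal antibodies, high-potency carcinogen classes (N-nitroso,
azoxy, aflatoxin-like) and bioaccumulative polyhalogenated scaffolds
are excluded. The `alerts` module screens SMILES structures against a
data-driven SMARTS catalogue and these rules.

## Worked example

```python
>>> import ttcrisk as tr
>>> pod = tr.PointOfDeparture()              # 1.5 μg/day @ 1:100,000, 70 y
>>> mli = tr.compute_mli(pod)
>>> mli
38325.0
>>> t_ex = tr.lifetime_exposure_days(tr.ExposureScenario(40, 240))
>>> tr.compute_adi(mli, t_ex).as_dict()
{'mli_ug': 38325.0, 't_ex_days': 9600, 'ecr': None,
 'adi_exact': 3.9921875, 'adi_reported': 4.0}
```

A 40-year working life at 240 exposure days/year gives 9600 exposure
days, so the lifetime budget of 38,325 μg becomes 3.9921875 μg/day,
reported (two significant figures) as **4 μg/day** at the unchanged
1:100,000 risk. Raising the acceptable risk to the German TRGS 910
tiers scales the limit linearly:

```python
>>> tr.adjust_adi(mli, t_ex, tr.RISK_POLICY_PRESETS["trgs_acceptance"], pod).reported_value
16.0
>>> tr.adjust_adi(mli, t_ex, tr.RISK_POLICY_PRESETS["trgs_tolerance"], pod).reported_value
1600.0
```

The adopted 4 μg/day (= 4000 ng/day) over 200 cm² of exposed skin gives
the surface threshold, and the bundled review of 27 published
wipe-sampling studies shows real facilities sit below it:

```python
>>> tr.compute_ascl(4000, 200)
20.0
>>> records = tr.load_reference_survey().records
>>> tr.summarize(records)["max_mean"]          # highest reported mean, ng/cm²
17.4
>>> tr.compute_ddi(17.4).ddi                   # worst-case intake, ng/day
3479.9999999999995
>>> tr.assess_safe(3480, 4000)
{'risk_ratio': 0.87, 'verdict': <Verdict.SAFE: 'safe'>}
```

The highest mean contamination on record (17.4 ng/cm²) implies a daily
dermal intake of ~3480 ng/day — below the 4000 ng/day limit (risk ratio
0.87), so routine contamination in modern facilities does not exceed
the acceptable risk level.

Structural screening:

```python
>>> panel = tr.load_reference_panel()
>>> out = tr.screen_panel(panel)
>>> out["exclusion_counts"]
{'n_nitroso': 3, 'metal': 4, 'protein': 2, 'azoxy': 1,
 'aflatoxin_like': 1, 'polyhalogenated_scaffold': 2}
```

The same operations are available from the shell:

```
ttcrisk adi --years 40 --days-per-year 240 --risk 4:100000
ttcrisk ascl --adi 4
ttcrisk ddi --sc 17.4 --adi 4
ttcrisk screen drugs.smi --out results.json
ttcrisk assess survey.csv --ascl 20
ttcrisk simulate --seed 1 --out campaign.csv
```

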