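# intrisol

Intrinsic aqueous solubility of drug-like molecules: derivation from
pH-dependent assays, multi-task graph-transformer prediction, and pH 0–12
solubility profiles.

Most high-throughput solubility assays measure *total* solubility at a
working pH (typically pH 2 and pH 7), which for ionizable compounds can sit
orders of magnitude above the intrinsic solubility S0 of the neutral
species.  `intrisol` is for computational and pharmaceutical chemists who
need the three steps around that fact:

1. **Curation** — turn raw assay records plus predicted pKa's into an S0
   dataset using Henderson–Hasselbalch speciation,
   `S(pH) = S0 · Φ(pH)` with
   `Φ(pH) = 1 + Σ_k 10^(k·pH − Σ_{j≤k} a_j) + Σ_k 10^(Σ_{j≤k} b_j − k·pH)`,
   inverted at the least-ionized measured pH, with rules for ampholytes,
   zwitterions (discarded when min aᵢ − max bⱼ ≤ 2), salts, censoring at
   the 0.1–600 µM dynamic range, and replicate disagreement (≥ 0.7 log
   units drops the compound; otherwise the smaller solubility wins).
2. **Prediction** — a multi-task graph transformer (GINE message passing +
   global attention modulated by an exponential decay mask γ^d(i,j) over
   hop distances, random-walk structural encodings) trained with a
   homoscedastic-uncertainty-weighted loss on eight tasks: S0, solubility
   at pH 2 / pH 7 / FaSSIF, logP, and logD at pH 2.6 / 7.4 / 10.5.
3. **Profiles** — reconstruct log S over pH 0–12 from predicted S0 and
   pKa's; points where more than 3 pKa's impact solubility are marked
   undetermined.  Profiles from two S0 values differ by exactly their S0
   difference, so an S0 prediction error shifts the curve rigidly.

A synthetic-data generator reproduces the statistical structure of a
high-throughput screen (noise, censoring, solid-state labels, salt forms,
sparse task matrix), so the entire workflow runs end to end without any
proprietary data.  See `docs/methods.md` for the models and assumptions.

## Worked example

`examples/` contains one short script per capability.  Curating a simulated
300-compound screen (`python examples/02_simulate_and_curate.py`):

```
simulated 300 compounds, 650 assay records
status
ok                        168
no_records                 99
salt                       15
zwitterion                 10
duplicate_disagreement      7
missing_ph7                 1
168 S0 values derived, 166 high-quality
median |derived - true| = 0.199 log units
```

168 of 300 compounds survive the filters (the rest fall to censoring or
missing crystalline records, salt forms, the zwitterion gap rule, or
replicate disagreement), and with 0.3 log units of simulated assay noise
the derived S0 values sit a median 0.20 log units from the generator's
truth.  Speciation itself (`python examples/01_speciation.py`):

```
log10 Phi at pH 7 for a base with pKa 9: 2.00432
log10 S(pH 7) for log10 S0 = -6:        -3.99568
inverted back to intrinsic S0:          -6.00000
```

Two pH units below its pKa a base is ~99% protonated, so total solubility
is ~100× the intrinsic value; the inverse map recovers S0 exactly.  The
other examples cover training (`03`), pH profiles and the constant-offset
property (`04`), and the five-trial mean (SD) evaluation protocol (`05`).

The same stages are available as a thin CLI for batch use:

```sh
intrisol simulate --n 500 --seed 0 --out data/
intrisol curate   --records data/records.csv --aux data/aux_tasks.csv --out data/
intrisol train    --table data/task_table.csv --out model.npz
intrisol predict  --model model.npz --input compounds.csv --out preds.csv
intrisol profile  --input s0_pkas.csv --out profiles.csv
intrisol evaluate --table data/task_table.csv --trials 5
```

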