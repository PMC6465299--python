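# hergqc

Quantitative analysis of hERG (Kv11.1) potassium-channel proteostasis: how
endoplasmic-reticulum quality control (ER QC) and peripheral (post-ER)
quality control jointly determine the cell-surface expression of
disease-associated channel variants.

Loss-of-function mutations in hERG cause Long-QT syndrome type 2, most often
not by breaking channel gating but by triggering recognition and degradation
of partially functional channels. Mildly misfolded variants (e.g. in the
cytosolic PAS domain) escape the ER in substantial amounts yet still express
poorly at the plasma membrane, because a second line of quality control
removes them from the cell surface: accelerated endocytosis, impaired
recycling and lysosomal delivery. This package provides, for workers in
membrane-protein trafficking and channel pharmacology:

* a **compartmental kinetic simulator** of the standard assay panel
  (metabolic pulse-chase, surface-ELISA internalization/turnover,
  sandwich-ELISA recycling, cycloheximide chase, per-vesicle pH sets), with
  seeded, reproducible measurement noise;
* the **assay estimators**: maturation efficiency FG₃/(CG₀ − CG₃),
  plateau-zero single-exponential decay fits (T½ = ln 2 / k), percent
  internalized per 5 min, recycling percent, isotype-background subtraction,
  mRNA/wild-type normalization, 2^−ΔΔCt transcript quantification,
  temperature fold-change, ubiquitination index;
* **FRIA analysis**: multi-Gaussian fits of vesicular-pH histograms and the
  area-weighted mean pH statistic;
* the **ER-vs-peripheral decomposition** of each mutant's surface-expression
  loss: er_loss = 100·(1 − me_rel), peripheral_loss = 100·(me_rel − pm_rel),
  where me_rel and pm_rel are maturation efficiency and surface expression
  relative to wild type — under the null model that a purely ER-limited
  mutant expresses in proportion to its maturation efficiency;
* a **sorting-motif scanner** (YxxΦ, acidic dileucine, KFERQ-related,
  caveolin- and ALIX-binding signals) with optional restriction to annotated
  cytosolic regions.

Because no raw data are deposited for this system, presets for the wild type
and eight PAS-domain mutants are *calibrated*: the shipped YAML stores the
published assay readouts and the package inverts its own estimators to find
the rate constants that reproduce them (see `docs/methods.md`).

## Worked example

```python
from hergqc import NoiseModel, load_presets, simulate_pulse_chase, simulate_surface_pools
from hergqc import estimators

lib = load_presets()
wt = lib.params("WT")   # readouts -> rate constants, calibrated on first use
print(f"calibrated WT rates: k_mat={wt.k_mat:.3f}/h  k_erad={wt.k_erad:.3f}/h  "
      f"k_int={wt.k_int:.4f}/min  k_rec={wt.k_rec:.4f}/min  k_lys={wt.k_lys:.4f}/min")

noise = NoiseModel(cv_band=0.1)                      # 10% densitometry noise
table = simulate_pulse_chase(wt, noise, n_reps=3, seed=7)
res = estimators.maturation_from_table(table)
print(f"WT maturation efficiency: {res.mean_pct:.1f} +/- {res.sem_pct:.1f} % "
      f"(n={len(res.per_replicate_pct)})")

t65p = lib.params("T65P")
course = simulate_surface_pools(t65p, (1.5, 3.0, 4.5, 6.0), "turnover",
                                NoiseModel(cv_well=0.08), seed=7)
fit = estimators.surface_decay_fit(course)
print(f"T65P surface half-life: {fit.half_life:.2f} h (R^2={fit.r_squared:.3f})")
```

Output:

```
calibrated WT rates: k_mat=0.489/h  k_erad=0.311/h  k_int=0.0123/min  k_rec=0.0542/min  k_lys=0.0100/min
WT maturation efficiency: 49.2 +/- 2.9 % (n=3)
T65P surface half-life: 2.41 h (R^2=0.991)
```

The wild type converts half of its ER-departing nascent pool into mature
channel and persists ~7 h at the surface; the T65P mutant matures at 23%
efficiency and is cleared from the surface roughly three times faster — the
discrepancy between those two defects is what the decomposition attributes
to peripheral QC. Note the same WT parameter set produces both ~5% surface
loss per 5 minutes and a 7-hour half-life: rapid internalization is mostly
balanced by recycling (k_rec ≫ k_lys), so the long-term decay follows the
slow eigenvalue of the surface/endosome system.

A command-line front end covers the same flow:

```bash
hergqc simulate --construct WT --assay pulse-chase --seed 1 --out out/
hergqc fit --assay pulse-chase --in out/pulse_chase.csv --out out/fit.csv
hergqc fria --in vesicles.csv --out fria_summary.csv
hergqc decompose --in summary.csv --wt WT --out decomposition.csv
hergqc scan-motifs --fasta channel.fasta --topology cytosolic.tsv --out hits.tsv
hergqc run --constructs WT,T65P,F29L --seed 1 --out report/
```

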