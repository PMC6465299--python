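# Methods

## The model

`hergqc` quantifies how two protein quality-control (QC) systems jointly set
the cell-surface expression of hERG (Kv11.1) potassium-channel variants: ER
quality control, which retains and degrades misfolded nascent channels, and
peripheral (post-ER) quality control, which removes mature channels from the
plasma membrane via accelerated endocytosis, impaired recycling and lysosomal
delivery.

Two linear compartmental subsystems are solved in closed form.

**Biosynthetic cascade** (hours time base). A pulse-labeled cohort of
core-glycosylated (CG, immature) channel leaves the ER pool at the total
nascent decay rate K = k_mat + k_erad, splitting between maturation (k_mat,
appearing as the complex-glycosylated FG form) and ER-associated degradation
(k_erad). The mature pool decays at k_pm:

    CG(t) = exp(-K t)
    FG(t) = k_mat / (K - k_pm) * (exp(-k_pm t) - exp(-K t))

with the removable singularity at K = k_pm handled by its limit
k_mat · t · exp(-K t). Degraded material is tracked explicitly so all four
pools sum to the initial cohort exactly (mass balance is a tested invariant,
tolerance 1e-9).

**Surface/endosome exchange** (minutes time base). An antibody-labeled
surface cohort obeys

    dS/dt = -k_int S + k_rec E
    dE/dt =  k_int S - (k_rec + k_lys) E,   S(0) = 1, E(0) = 0.

The eigenvalues of this system reconcile the seemingly contradictory surface
readouts: the fast mode (~k_int + k_rec + k_lys) governs the 0–7 min
internalization assay, while the slow mode |λ_slow| ≈ k_int·k_lys/(k_int+κ)
governs the multi-hour surface half-life. A channel can lose 5% of its
surface pool per 5 minutes yet have a 7-h half-life because most internalized
channel recycles. The recycling assay pre-loads the endosomal pool by a
20-min uptake phase and reports the cumulative recycled fraction
f_rec·(1 − exp(−(k_rec+k_lys) t)) with f_rec = k_rec/(k_rec+k_lys);
re-internalization of recycled channel within the ≤20-min window is
neglected.

**Temperature.** Cycloheximide (CHX) chases probe mature-pool stability; the
mature band decays at k_pm at 37 °C and k_pm·temp_factor at 41 °C. The
temperature factor is applied to k_pm only: whether internalization itself
accelerates at 41 °C is not separable from the available readouts.

## Parameters

| Parameter | Units | Meaning | WT calibrated value |
|---|---|---|---|
| k_mat | /h | ER maturation/export | 0.489 |
| k_erad | /h | ERAD of nascent pool | 0.311 |
| k_int | /min | internalization | 0.0123 |
| k_rec | /min | endosome→surface recycling | 0.0542 |
| k_lys | /min | endosome→lysosome sorting | 0.0100 |
| k_pm | /h | mature-pool degradation (37 °C) | 0.0990 |
| temp_factor | – | k_pm multiplier at 41 °C | 1.1 |

Rate constants are never stored: the source study reports assay readouts, so
each preset stores the readouts (maturation efficiency %, % internalized per
5 min, % recycled at 10 min, surface half-life) and `calibrate_preset`
inverts the package's own noiseless simulate→estimate pipeline to obtain the
rates, verifying every target is reproduced to 1e-4 relative. Two
identifiability choices close the system:

* **k_pm = ln 2 / T½(surface).** The mature pool's metabolic decay is
  equated with its surface turnover — both assays probe elimination of the
  same mature cohort.
* **K = k_mat + k_erad is fixed per preset** (default 0.8/h, CG half-life
  ~52 min, leaving ~9% of the CG pool after the 3-h chase, consistent with
  near-complete CG disappearance on the source gels). The individual split
  between k_mat and k_erad then follows from the maturation-efficiency
  readout, which is linear in k_mat at fixed K. Fixing instead the total
  label remaining at 3 h is not possible for the wild type: with maturation
  efficiency calibrated to 50%, CG₃+FG₃ = 0.5 + 0.5·exp(−3K) exceeds 50% for
  every K, so a ~35% remaining-label constraint is unattainable and the
  nascent decay rate is fixed directly instead.

Peripheral rates are found by bounded least squares (log-parameterized,
multi-start from a coarse eigenvalue-matched grid) against the
internalization, recycling and half-life readouts computed by the actual
estimators on noiseless simulations; mutually incompatible targets (e.g. a
half-life implying net surface decay faster than gross internalization)
raise an explicit infeasibility error naming the violated bound.

Preset readout provenance is annotated in `data/presets.yaml`: values printed
in the study text are used as printed (WT 50% maturation, ~5%/5 min, ~7 h,
1.1-fold; F29L 9% → 21% with E4031; T65P 23% → 35%; vesicular pH 6.69 / 5.4 /
6.67); per-construct values the study shows only as ranges are documented
mid-range choices; the WT recycling percentage (figure-only) is a flagged
placeholder at 40%/10 min.

## Measurement model

Densitometry bands and ELISA wells receive independent multiplicative
lognormal noise with unit mean (cv_band = 0.10, cv_well = 0.08 by default,
quadruplicate wells). Pulse-chase replicates carry their own labeling
amplitude, which cancels in the within-replicate maturation ratio. Specific
ELISA wells include an additive isotype background (5% of the initial
specific signal by default); dedicated background wells let the estimator
subtract it, clamping negative corrected means to zero with a logged count.
Vesicular pH per (construct, condition, chase time) is specified by explicit
Gaussian-mixture tables in the preset file — the late-compartment
acidification (~6.0 → 4.8 over the chase) is not kinetically specified by
the trafficking model — and per-vesicle draws are truncated to pH 3.5–8.0.

## Estimators and numerical choices

* **Maturation efficiency** = 100·FG₃/(CG₀ − CG₃), computed per replicate,
  then mean ± SEM across replicates (n ≥ 3 convention). The ratio is
  scale-invariant to gel exposure. CG₃ ≥ CG₀ is an error, not a silent NaN.
* **Exponential decay fits** use unweighted least squares on linear-scale
  signals with plateau fixed at 0 (eventual complete degradation), A and k
  bounded non-negative, initialized from a log-linear regression. A fitted
  decay below 1e-4 of the signal over the observed span is reported as flat:
  rate 0 and an infinite half-life sentinel. Non-convergence sets a flag
  rather than returning silent zeros.
* **Percent internalized** at 5 min is evaluated from the fitted curve over
  the 0–7 min window, 100·(1 − e^(−5k)), not from raw interpolation.
* **Rates are combined on the rate scale.** When several runs are averaged,
  the summary half-life is ln 2 / mean(k̂): fitted rates are recovered
  unbiasedly, while per-run half-lives (reciprocals) have a heavy right tail
  that distorts small-sample means.
* **Paired temperature chases.** The 41/37 °C fold is computed from chase
  pairs sharing one blotting-noise realization (dishes processed on the same
  gel); with unpaired noise the mean per-pair rate ratio carries a Jensen
  bias of roughly +0.06 at cv 0.1, comparable to the effect being measured.
* **FRIA.** Per-vesicle pH is histogrammed in 0.1-pH bins aligned to
  multiples of the bin width (width exposed as a parameter). A sum of 1–3
  Gaussian peaks is fit to the bin counts by bounded least squares with
  quantile-based starts; in automatic mode an extra peak is accepted only if
  it improves the fit under a nested-model F-test at α = 0.01 — information
  criteria on binned counts systematically overfit here. Component weights
  are the peak areas (amplitude·sd) normalized to one: areas represent
  vesicle counts, so the summary mean pH is the area-weighted average of
  peak centers. A single-occupied-bin histogram returns a degenerate
  component with sd floored at half the bin width and a flag. An optional
  fluorescence-ratio front end maps ratios to pH by monotone piecewise-linear
  interpolation, clamping out-of-range ratios to the endpoints with a logged
  warning.
* **QC decomposition.** Relative to wild type, er_loss = 100·(1 −
  min(me_rel, 1)), total_loss = 100·(1 − pm_rel), peripheral_loss = total −
  er (exactly additive by construction). Mutants maturing faster than WT are
  clamped to me_rel = 1 for the partition, with the surplus visible as a
  negative peripheral loss; the stability flag compares pm_rel against
  me_rel with a 1e-6 neutrality tolerance. Rows order by increasing total
  loss, ties alphabetical. ER and peripheral QC responses are 1/me_rel and
  the turnover fold; me_rel = 0 yields an infinite-fold sentinel with a
  flag. Optional nonparametric bootstrap over replicates provides percentile
  intervals (off by default).
* **qPCR** uses (1+E)^(−ΔΔCt) with efficiency E = 1 by default (classic
  2^−ΔΔCt), exposed as a parameter.
* **Motif scanning** reports all overlapping matches with 1-based
  coordinates. Patterns live in `data/motifs.yaml`: tyrosine Y-x-x-Φ with
  Φ ∈ {L,I,M,F,V}; acidic dileucine [DE]-x-x-x-L-[LI]; caveolin-binding
  Φ-x-Φ-x₄-Φ or Φ-x₄-Φ-x-x-Φ with Φ ∈ {F,W,Y}; ALIX Y-P-x(1–3)-L. The
  KFERQ-related (chaperone-mediated autophagy) class is compositional: a
  pentapeptide containing a glutamine whose remaining four residues are
  fully accounted for by 1–2 basic {K,R}, 1–2 hydrophobic {F,I,L,V} and at
  most one acidic {D,E}. Topology filtering keeps hits whose entire peptide
  lies inside an annotated cytosolic interval.

## What the generator emulates — and what it does not

The generator reproduces the *measurement process* of each assay —
first-order compartment kinetics, replicate structure, multiplicative
densitometry/well noise, isotype background, mixture-distributed vesicular
pH — under the study's printed conditions. It does not emulate: plate-level
correlated noise or edge effects; saturation or nonlinearity of
chemiluminescent detection; cell-to-cell heterogeneity; partial ER exit of
the labeled cohort during the 30-min pulse (the cohort starts fully
core-glycosylated at t = 0); re-internalization of recycled channel during
the recycling readout; any mechanistic link between k_lys and vesicular pH
(mixtures are tabulated per chase time); or drug binding as a process (E4031
and low-temperature rescue are alternative parameter sets, reflecting
co-translational action). Passing tests therefore demonstrate that the
estimators recover known ground truth under idealized but realistically
noisy conditions — not that the rate constants are the true cellular values,
which are not identifiable from the printed readouts alone.

## Statistical power of the stochastic checks

Problem sizes follow the study conditions: 100 pulse-chase replicates for
maturation recovery, 10 ELISA runs for surface kinetics, 500 vesicles per
FRIA set, 50 paired CHX chases. At these sizes the recovery statistics have
standard errors of ~0.7 points (maturation), ~0.35 h (half-life), ~0.04 pH
(mean vesicular pH) and ~0.004 (temperature fold). The 5-min internalization
statistic is the least powered: a 5% true decay read against 8% well noise
gives a per-run fitted-percent sd of ~2.9 points, hence ~0.9–1.1 points for
the 10-run mean — the same order as its ±1-point recovery band, so
individual seeded draws of that check can honestly fall outside the band
(the estimator itself is unbiased; see `tests/` for the verification at
larger n).

## Known limitations

* The single-endosome recycling model cannot represent distinct fast/slow
  recycling routes; f_rec and κ are effective aggregates.
* Maturation-efficiency estimates carry a small positive Jensen bias
  (~+0.8 points at cv 0.1) because the denominator CG₀ − CG₃ is noisy; this
  is a property of the ratio estimator itself, reproduced faithfully.
* k_erad and k_mat are only jointly identified given the fixed nascent decay
  rate; alternative K values rescale both without changing any simulated
  readout except the CG₃ band fraction.
* Mixture fits with fewer than ~20 vesicles fall back to a single component;
  heavily overlapping components (Δmean < ~1.5 sd) may be merged by the
  F-test, which biases component counts low but leaves the weighted mean pH
  (the reported statistic) nearly unaffected.
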