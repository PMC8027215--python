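# Methods

## Buoyant-density model

A nucleic-acid species is characterized by its GC content and the ¹³C atom
fraction *a* of its carbon. Its equilibrium band center in the gradient is

    ρ(GC, a) = ρ₀(GC, medium) + a · Δρ_max(medium)

- **DNA in CsCl**: ρ₀ = 1.660 + 0.098·GC g/ml (the Schildkraut linear
  relation). Both coefficients are keyword-configurable.
- **RNA in CsTFA**: ρ₀ = 1.780 g/ml, constant by default. rRNA GC spans
  only ~50–60 mol%, too narrow to move the band materially; an optional
  weak GC slope (anchored at GC = 0.55) is exposed for sensitivity
  analyses.
- **Full-label shift**: Δρ_max = 0.036 g/ml (DNA) and 0.035 g/ml (RNA),
  linear in *a*. Linearity is the simplest model consistent with heavier
  banding reporting a higher degree of labelling; the maxima are
  literature-typical values for complete ¹³C substitution.

The band is Gaussian with standard deviation `band_sigma` (default
0.004 g/ml; band spread is not constrained by the data this package
targets, so it is a free parameter). The gradient is discretized into 13
fractions, heaviest first, on linear density grids 1.830→1.750 g/ml (RNA)
and 1.740→1.660 g/ml (DNA). Fraction intervals are midpoints between
consecutive fraction densities, open-ended at both tails, so band mass is
conserved; per-fraction masses are exact Gaussian-CDF differences (tested
against brute-force quadrature to 1e-6).

## Synthetic sequencing model

`simulate_gradient` computes each taxon's abundance-weighted band mass per
fraction, renormalizes within the fraction, and draws read counts from a
multinomial at `read_depth` (default 50 000) per fraction. Fractions whose
total nucleic-acid mass falls below `template_floor` (default 1e-4 of
total community nucleic acid) are marked *missing* — library preparation
fails, emulating fractions for which cDNA synthesis yields nothing. All
randomness flows through one integer seed.

What this emulates: compositional (total-sum-scaled) fraction profiles,
sampling noise at realistic read depths, dropout of low-template
fractions, and the RNA-SIP practice of pooling fraction pairs (4+5, 6+7,
8+9, 10+11; pooled density = mean of members) before sequencing. What it
does not: PCR and extraction biases, chimeras, taxonomy error, diffusive
band asymmetry, gradient-to-gradient density jitter, or read-level
sequence simulation. Passing the recovery tests therefore shows the
classifier is correct and well-calibrated *given* the banding model, not
that real amplicon workflows are free of these other error sources.

Calibration standards are simulated differently, and deliberately so: a
standard is a single species whose *mass profile across fractions* is the
informative signal (in the laboratory it is quantified per fraction, not
sequenced compositionally — total-sum scaling of a one-species gradient
would be identically 1 and carry no information). `simulate_standards`
therefore distributes `read_depth` quanta over the 13 fractions in
proportion to band mass and returns unscaled single-row tables;
`calibrate` rejects scaled input.

## Classification procedure

Tables are total-sum-scaled per fraction; "5 % increase" is read as 5
percentage points of relative abundance (`delta_points`, default 5),
compared strictly (an exact 5.0-point difference fails, with a 1e-9-point
epsilon so float round-off cannot flip the tie). Criterion 1 compares the
heavy-window maximum of the labelled gradient against the OTU's maximum
over *all* control fractions — the most conservative reference. Criterion
2 compares heavy vs light maxima within the labelled gradient; all
sub-threshold fractions count as light. Both must pass (AND gate) for
OTUs with control background at or above `background_floor` (default
0.001 relative abundance); below that, the OTU is routed to the presence
rule — detection above the floor in any heavy fraction — because a
percentage-point increase over an undetectable background is not
meaningful. The 0.001 gate is a judgment call and configurable.

The heavy threshold comes from standards: the lowest density at which the
labelled standard holds at least `floor` (1 %) of its total mass and
exceeds the unlabelled standard by `ratio` (2×). On the default simulated
standards this lands within one fraction width of 1.797 g/ml (RNA); when
no standards are supplied, fixed thresholds 1.797 g/ml (RNA) and
1.702 g/ml (DNA) are used. Strong labelling starts at `strong_density`
(fixed 1.816 g/ml RNA, 1.714 g/ml DNA; for standards-derived calibrations
the same offsets above the derived threshold, 0.019 and 0.012 g/ml). The
RNA strong cutoff reflects where near-fully labelled RNA bands; the DNA
cutoff is the threshold plus roughly two fraction widths, since nothing
sharper is identifiable. Labelled calls are graded by the density of the
OTU's peak-abundance fraction.

GC confound: a labelled call for a taxon whose *unlabelled* nucleic acid
would already band at or above the threshold (for DNA, GC ≳ 0.43 under
the default map) is flagged with a warning rather than trusted — heavy
presence could then be pure base composition. Low-GC archaeal DNA
(GC ≈ 0.30 bands at 1.6894 g/ml) is safely below the 1.702 g/ml window,
which is exactly why DNA-SIP works for such taxa.

No multiple-testing correction is applied: the procedure is fixed
thresholds, not hypothesis tests. Replicate gradients are classified
independently; consensus across replicates is left to the caller.

## Benchmark community

`reference_community()` fixes the recovery benchmark: ten DNA-SIP taxa
with GC 0.28–0.40 (low-GC sediment archaea; no unlabelled member reaches
the CsCl heavy window), abundances 0.05–0.20, and ¹³C atom fractions 0
(six taxa), 0.4 (two — the mixotrophic level the atom-tracing model
predicts) and 1.0 (two). DNA is used as the benchmark medium because the
0.4 band (≈1.704 g/ml at GC 0.30) falls cleanly between the 1.702
threshold and the 1.714 strong cutoff; on RNA the corresponding band
(1.794 g/ml against a 1.780 baseline) straddles the 1.797 threshold, so
RNA assertions about the 0.4 level are ordering-only. Recovery and
specificity are measured over 100 seeded simulation pairs at 50 000 reads
per fraction — sizes at which multinomial noise (≈0.2 points) is far from
the 5-point criteria, so the tests probe the logic, not luck.

## Atom tracing

Metabolites are ordered tuples of per-carbon ¹³C probabilities —
expectations, not full isotopologue distributions, which suffices because
band position responds only to the mean atom fraction. Operations conserve
carbon except where a carbon is explicitly removed. Pyruvate synthesis
appends one DIC-derived carboxyl carbon to acetyl-CoA (mean label
(ΣC + d)/3, hence 1/3 for unlabelled acetyl and d = 1). Ribose formation
condenses two trioses into a hexulose and removes the formaldehyde-derived
carbon; which hexulose position leaves is set by `formaldehyde_position`
(default: an organic-derived, hence unlabelled, carbon — the only
assignment consistent with the 33 % → 40 % enrichment step; only aggregate
labels are asserted, positional assignments within the hexulose are not
identifiable from band data). Lactate→pyruvate preserves positions. The
autotrophic scenario assumes every ribose carbon is DIC-derived (a
complete Wood–Ljungdahl route); partial-pathway variants are out of scope.

Predicted band class for a traced atom fraction uses a typical unlabelled
baseline — 1.784 g/ml for rRNA (mid-range GC), the Schildkraut value at
GC 0.30 for DNA — plus the linear shift, binned against the calibration.
The 0.40 RNA prediction sits ~1 mg/ml above the threshold: genuinely
calibration-sensitive, which mirrors how mixotrophic RNA appears in
partially labelled rather than heavy fractions.

Isotope conversions use R_VPDB = 0.0111802; δ¹³C ↔ atom fraction are
exact inverses on (−1000, ∞) ‰. `mix_toc` is a two-pool mass balance on
atom fractions (not on δ values, which are not conservative at high
enrichment).

## Numerical and degenerate-input choices

- Strictly decreasing densities are enforced (tolerance 1e-12); ties are
  rejected rather than reordered.
- Missing fractions are NaN columns with an explicit flag, never zeros;
  all-zero columns become missing on scaling; pooling any missing member
  yields a missing pooled column.
- `band_sigma → 0` degenerates gracefully (all mass in the interval
  containing the band center); σ = 0 itself is rejected.
- Criteria maxima over empty windows are 0, so an all-light gradient
  yields only unlabelled calls.
- Peak-density ties resolve to the heavier fraction (first in column
  order).

## Known limitations

- The GC→density and shift→atom-fraction maps are linear idealizations;
  the package classifies labelling, it does not invert observed density
  shifts into per-taxon atom-fraction estimates (no quantitative-SIP
  estimator).
- No differential-abundance statistics: thresholds, not tests, so no
  error-rate guarantees beyond the simulated specificity checks.
- The CsTFA RNA baseline and the strong cutoffs are tied to the default
  grids; users with different gradient media or rotors should recalibrate
  with their own standards.
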