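# Methods

## The damage estimator

The assay quantifies polymerase-blocking lesions (strand breaks, abasic
sites, bulky photoproducts — anything that stops the polymerase) by
comparing amplification of a long (a = 3494 bp) and a nested short
(s = 66 bp) fragment of the mouse LINE-1 ORF2 region. Writing E_L, E_S
for the per-cycle amplification efficiencies, the normalised
amplification ratio of sample *s* against *n* controls is

    R(s) = E_L^CtL(s) · E_S^−CtS(s) / [ Π_c E_L^CtL(c) · E_S^−CtS(c) ]^(1/n)

and the damage estimate is `10^4 · (R^(1/a) − 1)` lesions per 10 kb.
`lordq` evaluates the exponent in log space,

    lesions = 10^4 · expm1( [ ln E_L · (CtL(s) − mean_c CtL)
                              − ln E_S · (CtS(s) − mean_c CtS) ] / a ),

replacing the geometric mean over controls by an arithmetic mean of
control Cts. The two forms are algebraically identical; the log-space
form avoids overflow of E^Ct products for large Ct or many controls and
is verified against direct evaluation of the product form to relative
1e-10 in the tests. `expm1` keeps precision when R ≈ 1.

Assumptions inherited from the assay: controls are damage-free (so
estimates are relative to the controls' baseline, and mildly damaged
controls shift everything down); lesions are uniformly distributed over
the genome so L1 damage is representative; the short fragment is short
enough that damage to it is negligible (see the bias discussion below).

### Replicate handling

Wells run in triplicate are collapsed to an arithmetic mean Ct per
sample and target before the formula. Censored wells ("undetermined":
no threshold crossing within the 40-cycle programme) are excluded from
the mean; a sample whose long-fragment wells are all censored is
reported as unquantifiable — damage above the assay's dynamic range —
rather than mapped to a numeric sentinel. An optional QC flag drops a
replicate more than 0.5 cycles from the replicate median; it is off by
default. Negative estimates are reported as-is; clamping at zero would
bias group means upward.

## Standard curves

Each plate carries a 7-point two-fold dilution series of a plasmid copy
number standard, 5×10⁵ down to 7812.5 copies. Triplicate wells are
averaged per point, then mean Ct is regressed on log10(copies) by
ordinary least squares; efficiency is `10^(−1/slope)` (the universal
qPCR convention: slope −3.32 ⇔ perfect doubling). A non-negative slope
marks the curve invalid. Fitted curves from a standards table override
the configured default efficiencies (E_L = 1.82, E_S = 1.98, the
assay's published means); the provenance of the pair used is recorded
with every result. Efficiencies in (2.0, 2.2] are tolerated with a
warning as standard-curve noise; values outside (1, 2.2] are rejected.

Absolute quantification inverts the short-fragment curve,
`copies = 10^((Ct − intercept)/slope)`, and scales by lysate/template
volume (defaults 40 µl and 2 µl, i.e. 20×) to whole-cell copies. A Ct
outside the fitted range triggers an extrapolation warning: with one
cell per 40 µl lysate a well holds ~2,750 copies, somewhat below the
lowest standard point, so single-cell copy numbers are short
extrapolations of the curve — exactly as in the underlying assay design.

## Fragment-length conversion

Electrophoresis-derived mean fragment lengths L (bp) convert to
double-strand breaks as `10^4 / L` breaks per 10 kb. The published
sonication-series values 3.03 and 4.10 (from 3301 and 2438 bp) are
reproduced exactly; for 1982 bp the rule gives 5.045, which differs in
the third decimal from the published 5.04 — the upstream unrounded
length presumably differed — a ≤0.2% discrepancy the package documents
rather than special-cases.

## The simulator

The generator formalises the assay's two working assumptions: lesions
arrive as a homogeneous per-base Poisson process with rate λ (per bp),
and one lesion anywhere in an amplicon blocks amplification of that
template entirely. Hence for a cell with n0 template copies the
amplifiable count per target is Binomial(n0, exp(−λ·length)), drawn
once per cell per target because a single lysate feeds all replicate
wells — replicate scatter is therefore Ct noise only. Effective copies
map to Ct through exponential growth, `Ct = ln(Q/n_eff)/ln(E)` with
threshold quantity Q, plus Gaussian cycle noise; wells with no template
or Ct beyond the cycle limit come out censored. The true damage of a
simulated cell is 10⁴·λ.

Defaults emulate the assay's conditions: n0 = 55,000 L1 copies per
diploid cell, E_L = 1.82, E_S = 1.98, triplicate wells, a control group
plus three graded damage groups (3, 6, 9 lesions/10 kb — the shape of a
UV dose series; doses are opaque labels, not a photochemistry model),
12 cells per group, per-plate 7-point standards, 40 µl lysate with 2 µl
per well. Ct noise defaults to 0.2 cycles, typical qPCR replicate
scatter (the assay publishes none). Q = 10¹⁰ is arbitrary — it cancels
in the ΔCt statistic — and is chosen to keep Cts in the observed 15–35
window. Everything is driven by one seeded generator: identical configs
give bit-identical plates.

Because the short fragment is itself damageable (survival
exp(−λ·66)), the estimator's expectation under this model is

    E[lesions] ≈ 10^4 · (exp(λ(a−s)/a) − 1) ≈ 10^4 λ · (a−s)/a,

about 1.9% below the truth — the assay's known slight underestimation,
reproduced deliberately. A config switch (`short_fragment_damageable =
False`) idealises s → 0, and the tests confirm the bias disappears.

What the simulator does not emulate: pipetting/volume errors,
inter-plate batch effects, inhibitors and efficiency drift across
samples, non-Poisson (clustered) lesion spectra, primer-site damage, or
raw fluorescence curves (the model starts at Ct). Passing tests
therefore validate the estimator and its statistical behaviour under
the assay's own model of itself, not instrument-level robustness.

## Statistics

Group comparison uses the Kruskal–Wallis rank test (mid-ranks, tie
correction), with p from the chi-square approximation (df = k−1) —
standard for group sizes ≥ 5; a seeded Monte-Carlo permutation p-value
is available for tiny groups. If all pooled observations are identical
the test is defined as H = 0, p = 1. A Shapiro–Wilk screen per group is
reported for information only; the comparison stays nonparametric
regardless, with α = 0.05. Post-hoc pairwise Mann–Whitney tests with
Holm adjustment exist behind a flag and are off by default — the
omnibus test is the primary report. Asymptotic Kruskal–Wallis and
Shapiro–Wilk are delegated to scipy.stats behind this module's surface;
the permutation path recomputes the tie-corrected H directly and is
cross-checked against the library statistic in the tests.

## Numerical and design choices

- All Ct arithmetic is done at full precision as read; report tables
  round to 2 decimals for display only.
- Normalisation is within a user-declared control group per analysis
  run; cross-plate control pooling is the caller's choice of input.
- The interchange formats are plain delimited text (comma or tab,
  auto-detected); "undetermined"/"NA" mark censored wells. Readers
  validate schema, key uniqueness and target completeness and report
  offending line numbers.
- Exit codes distinguish input errors (2) from computational errors (3)
  in the CLI.
- Test problem sizes: the dose-response recovery check runs 100
  simulated experiments of 48 cells; efficiency recovery, 200 series
  per target; rank-test calibration, 2,000 null replicates; copy-number
  recovery averages 120 cells over 10 plates. These sizes put the
  Monte-Carlo error of each checked proportion well inside its
  acceptance margin while keeping the whole suite in seconds.

## Known limitations

- Efficiencies are taken from standard curves or configured defaults,
  never re-estimated from individual sample amplification kinetics.
- The estimator treats all polymerase-blocking lesion types as one
  class; lesion chemistry is out of scope.
- Single-run group means at 12 cells/group have a standard error of
  roughly 3% of the signal under default noise; per-plate fitted
  efficiencies add a further shared ~1% — claims about small biases
  need Monte-Carlo averaging over plates, as done in the tests.
- Copy-number estimates for single cells extrapolate slightly below
  the standard series and inherit the curve's intercept uncertainty
  (a few percent, shared within a plate).
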