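# Methods

## The model

The deterministic layer is the classical Håkanson potential-ecological-risk
construction. For element *i* with exposure concentration `C_i` (mg/kg dry
weight), background reference `C_n_i` (mg/kg, here the local study minima)
and a dimensionless toxic response factor `T_r_i` encoding relative
toxicity (Cd 30, As 10, Cu/Pb/Ni 5, Cr 2, Zn 1):

    C_f_i = C_i / C_n_i
    E_r_i = T_r_i · C_f_i
    RI    = Σ_{i=1..m} E_r_i

`m` counts the *eligible* elements — those with both `C_n` and `T_r`
established. In the packaged reference table Ni and As lack a background
and Co, Fe, Mn, V lack a toxic response; these are excluded from Er/RI and
listed in an exclusion report rather than being imputed. Class intervals
are half-open `[lower, upper)` with the value at a threshold assigned to
the upper class: Er at 40/80/160/320 (Low, Lower, Median, High, Extremely
high), RI at 150/300/600 (Low, Lower, Median, High).

The probabilistic layer replaces each `C_i` with a random variable and
propagates it through the same algebra by Monte Carlo: `Er_{i,j} =
T_r_i · C_{i,j} / C_n_i` for draws `j = 1..n`, `RI_j = Σ_i Er_{i,j}`, and
class probabilities are `100 · #{j in class}/n`. Exceedance curves report
`P(index ≥ v)` at every distinct simulated value, starting at 1.0 and
nonincreasing.

The fractionation layer is independent of the risk indices: five-step
sequential-extraction concentrations give percentage profiles computed
against the *summed extracted content* (the independent total digest is
used only for recovery QC), mobility orderings, and the retention
contamination factor `Cf = (F1+F2+F3+F4)/F5` (mobile over residual
content). This retention Cf and the Håkanson `C_f_i` are different
quantities with the same historical name; the API keeps them as two
separately named operations.

## Distribution fitting

Concentration laws come from two routes.

*From raw samples* (`fit_from_samples`): method-of-moments. Normal and
truncated-normal fits use the sample mean and sd (ddof = 1); the truncated
family takes the observed min/max as its support. Lognormal fits use the
log-sample moments. A constant sample degenerates to a point mass;
`empirical` stores the values for bootstrap resampling.

*From printed summaries* (`fit_from_summary`): when only min/max/mean are
available, the location is the mean and the SD comes from a heuristic —
the default is the range rule `(max − min)/4`, with `(max − min)/6` and an
explicit SD available. The default family is a **truncated normal on
[min, max]**: a plain normal generator can emit negative (physically
impossible) concentrations and values far outside the observed range,
while truncation preserves the printed support; the plain
normal-with-rejection family remains available to mirror a literal normal
generator. Rejection sampling treats the plain normal's effective law as a
normal truncated to [0, ∞) (∩ any support), and refuses specs whose
feasible mass is below 1%.

A consequence worth stating: the analytic mean of a truncated normal is
not its location parameter (for Zn on [66.6, 1095] with location 353 and
scale 257.1 the analytic mean is ≈ 415). Ground truth for parameter
recovery is therefore defined as the law's *analytic* mean and sd — the
quantities a moment fit estimates — not the location/scale parameters.

## Monte Carlo mechanics

- Iterations default to 100,000; probabilities are reported to 2 decimals.
- Rounding is half-even and applied only at the reporting layer; all
  internal arithmetic is unrounded. Class probabilities sum to 100 exactly
  before rounding and to 100 ± 0.05 after.
- One master seed deterministically derives a per-element substream keyed
  by the element *symbol* (not its position), so identical (inputs, seed)
  reproduce draws bitwise and adding an element never perturbs another
  element's stream.
- Er draws use the same floating-point association order as the
  deterministic index (`T_r · (C / C_n)`), and RI draws use
  correctly-rounded summation (`fsum`), so collapsing every law to a point
  mass reproduces the deterministic per-site assessment exactly — the main
  internal consistency check — and RI is invariant under element
  permutation.
- Elements are sampled independently by default; no dependence model is
  asserted by the data. A Gaussian-copula hook accepts a user-supplied
  correlation matrix (single shared stream, marginals via ppf) for
  sensitivity analyses.
- Distributions are fitted per element pooled over all sites; no
  stratification by river is attempted.

## Synthetic study generator

The generator emulates the study the published summaries describe — 32
sites on 15 Serbian rivers, 11 elements — with known ground truth:

- **Totals**: per element, n draws from the configured law; defaults are
  truncated normals anchored to the published min/max/mean with range-rule
  SD.
- **Hotspots**: the published outlier sites (Ibar: Cd/Zn/Pb/Ni; Pek:
  Cu/Zn; Porečka: Cu; West Morava: Pb; South Morava: Mn) get multiplied
  concentrations, `multiplier · max(draw, law mean)` with per-element
  multipliers of 3–10×, chosen so a hotspot provably exceeds the base
  law's 99th percentile for any seed.
- **Fractions**: per-element mean percentage profiles are designed so that
  ranking the means reproduces the published mobility orderings ("≈"-tied
  fractions get equal means; distinct ranks are ≥ 5 percentage points
  apart). Per-sample profiles add symmetric Gaussian noise of 3 percentage
  points per step (clipped at 0.1, renormalized) — enough scatter to be
  realistic while keeping the 32-sample study mean ordering stable. Steps
  are then rescaled to sum *exactly* to `total × recovery`, with the
  per-sample recovery drawn uniformly in [0.815, 1.14], mirroring the
  certified-reference accuracy range of the extraction.
- **Reference**: the packaged table.

What the generator does *not* emulate: spatial correlation between sites,
correlation between elements, instrument error structure beyond the
recovery factor, and any within-river stratification of concentration
levels (hotspots aside). Passing tests therefore demonstrate correctness
of the computational chain under a plausible data-generating process, not
agreement with the real rivers' unpublished per-sample values.

## Numerical and design choices

- Tie threshold for "≈" in orderings: 2 percentage points by default
  (configurable); with threshold 0 the ordering is the strict descending
  sort, and raising the threshold can only merge neighbours. Exact ties
  break deterministically by fraction index. Ordering equivalence compares
  tie groups as sets.
- `retention_cf` with a zero residual step raises an error instead of
  returning infinity: downstream statistics on Cf must not mix finite and
  infinite values. An all-zero profile is a degenerate-profile error.
- Recovery QC band defaults to [80%, 120%]; out-of-band samples are
  flagged, never dropped.
- Absent reference values are explicit nulls in the YAML config and `None`
  in memory; a zero would silently zero out Er.
- CSV round-trips are exact: floats are written as shortest-repr strings
  and parsed with round-trip precision.
- Classification at a threshold takes the upper class, matching the
  printed interval definitions (`40 ≤ Er < 80`, `150 ≤ RI < 300`).

## Problem sizes

The test suite simulates at n = 100,000 draws where a published
probability is checked and 20,000–50,000 for statistical property checks
(tolerance `3·√(p(1−p)/n)` per class); large-sample generator checks use
10,000 sites. The acceptance script draws 100,000 concentrations per
element.

## Known limitations

- The published class probabilities for Cd, Cu, As and Ni (and the RI
  table) depend on the unpublished per-sample data and on backgrounds not
  printed for Ni and As; they cannot be reproduced from the printed
  summaries and are deliberately not asserted. The package requires the
  user to supply Ni/As backgrounds explicitly before those elements enter
  Er/RI.
- The range-rule SD is a convention, not an estimate of the real study's
  dispersion.
- No geoaccumulation or pollution-load indices, no Bayesian parameter
  uncertainty, no spatial random effects.
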