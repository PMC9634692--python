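# Methods

## The kinetic model

`glykin` quantifies non-enzymatic, template-directed RNA copying chemistry
initiated from 2′(3′)-aminoacylated primers. A primer preparation made by
Flexizyme aminoacylation is a mixture: a fraction `p_gly0` carries the
amino acid ester (P_gly) and the rest is native RNA (P_rna,
`p_rna0 = 1 − p_gly0`). In the presence of a saturating activated
substrate (an imidazolium-bridged dinucleotide for extension, or an
imidazole-activated oligonucleotide for ligation) three irreversible
pseudo-first-order reactions compete:

```
P_gly  --k1-->  P_gly+1     extension via the amino group (N–P product)
P_gly  --k2-->  P_rna       hydrolysis of the aminoacyl ester
P_rna  --k3-->  P_rna+1     extension via the 3′-OH (O–P product)
```

The linear system

```
dP_gly/dt   = −(k1 + k2) P_gly
dP_rna/dt   =  k2 P_gly − k3 P_rna
dP_gly+1/dt =  k1 P_gly
dP_rna+1/dt =  k3 P_rna
```

has the closed form

```
P_gly(t)   = p_gly0 · e^{−(k1+k2)t}
P_gly+1(t) = p_gly0 · k1/(k1+k2) · (1 − e^{−(k1+k2)t})
P_rna(t)   = p_rna0 · e^{−k3 t}
           + k2 · p_gly0 · (e^{−(k1+k2)t} − e^{−k3 t}) / (k3 − (k1+k2))
P_rna+1(t) = 1 − P_gly − P_rna − P_gly+1
```

All rates are per hour and times are hours throughout; configurations may
not override the unit. Fractions are never clipped inside the math, so the
conservation invariant (the four fractions sum to 1 to 1e-9) is a real
test of the algebra, not of a clamp.

**Degenerate branch.** When `k3 = k1 + k2` the P_rna denominator vanishes;
the analytic limit `p_rna0·e^{−k3 t} + k2·p_gly0·t·e^{−k3 t}` is used
whenever `|k3 − (k1+k2)| < 1e-9·max(k3, k1+k2)`. The tolerance is far
below any experimentally resolvable rate difference and the tests verify
continuity of P_rna to 1e-6 across the switch.

`integrate_numeric` solves the same ODEs with LSODA at `rtol=1e-11`,
coded directly from the rate laws. It exists purely as an independent
oracle: the test suite checks closed form against it to better than 1e-6
on 100 randomized parameter sets with rates log-uniform in [0.01, 50] h⁻¹.

The asymptotic NP+1 yield `p_gly0·k1/(k1+k2)` (`branching_yield`) is the
branching ratio between productive extension and ester hydrolysis; it is
the quantity that determines how much amino-acid-bridged RNA a primer
pool can accumulate.

## Estimation

**k_obs (log-linear).** For simple first-order observables — native-RNA
extension or ligation (k3), ester hydrolysis (k2), bridged-oligo
hydrolysis — the observed rate is the slope of an ordinary least-squares
fit of `−ln(P/P0)` against time, with `P0` the first time point's
fraction. The intercept is left free: a small normalization offset at
t = 0 then lands in the intercept instead of biasing the slope, and the
intercept is reported as a diagnostic. Points with `P ≤ 0` cannot be
log-transformed and are rejected with the offending times named.
Half-lives are `ln(2)/k_obs`.

**k1 (nonlinear).** With `k2`, `k3` and `p_gly0` fixed from independent
measurements, `k1` is the single free parameter of a bounded least-squares
fit (`k1 ∈ [0, 10^4] h⁻¹`) of the closed-form solutions against the
observed bands: the co-migrating total-primer band against
`P_gly + P_rna`, and the NP+1 band against `P_gly+1` (extension gels) or
the unresolved ligation band against `P_gly+1 + P_rna+1` (ligation gels).
Residuals are unweighted and pooled across all points and replicates —
the simplest defensible choice given gel densitometry reports no
per-band variance. The optimizer restarts from {0.1×, 1×, 10×} a
slope-based initial guess (the pooled primer-decay k_obs), which removes
local-minimum risk cheaply for a one-dimensional objective. A fit whose
minimizer sits at a bound is flagged (`at_bound`), as is non-convergence;
neither is silently repaired. In the nonlinear fit, points with
non-positive primer fraction (possible after noisy normalization) are
excluded with a logged warning and a reported count rather than aborting
the fit.

**Ligation censoring.** The ligation product of aminoacylated primers
co-migrates with that of residual native primers, so the aminoacyl fit
uses only time points at which a matched pure-RNA control has produced
less than 2% ligated product (`censor_ligation`, threshold configurable).
Fitting the censored points against the `P_gly+1 + P_rna+1` model keeps
the procedure exact on synthetic data while mirroring the experimental
rule.

**Monte Carlo uncertainty.** The propagated error on `k1` is obtained by
refitting under draws of `(p_gly0, k2, k3)` from normal distributions
truncated at 0 (p_gly0 also at 1), with means and standard deviations
supplied by the user. Defaults: 1000 draws; the seed is mandatory, and
identical seeds give bitwise-identical summaries (median, sd, 16th/84th
percentiles). Refits start from the base estimate with a single optimizer
start — on this convex 1-D objective multi-starting every draw would only
cost time. If more than 20% of draws fail to converge the summary is
refused rather than reported.

## Gel quantification

Inputs begin at integrated band intensities (condition, replicate,
time_h, band, intensity); image analysis is upstream and out of scope, and
no background subtraction is applied — intensities are assumed
background-corrected by the densitometry software. Band intensity is
normalized within each lane (band / lane total), which cancels loading
differences exactly and converts intensities to species fractions. A
`BandMap` makes the species→band co-migration structure explicit and
auditable: extension gels resolve `primer` (both primer forms), `np1`,
`op1`; acidic hydrolysis gels resolve `primer_gly` and `primer_rna`;
ligation gels give `primer` and one unresolved `ligated` band. Every band
in a table must be claimed by exactly one observable, so an unexpected
band is a configuration error instead of silently distorting fractions.

## Synthetic data

The generators emit lane tables in exactly the schema the ingest path
reads, with a JSON manifest of the true parameters and seeds. They
emulate the features of the real assays that the estimators must cope
with:

- acylation yields drawn uniformly from 26–60% when not specified, one
  draw per design (technical replicates share the acylation prep);
- per-lane loading totals drawn lognormally (sd 0.2 around a mean of 10^4
  arbitrary units) so lane normalization is exercised non-trivially;
- multiplicative lognormal noise on each band (default sd 0.05, a
  placeholder magnitude — replicate variance is not characterized for
  this kind of densitometry — plus an optional additive baseline);
- the co-migration structure above, including the three-arm ligation
  experiment (aminoacyl arm, pure-RNA control arm with the same k3,
  hydrolysis arm for k2).

They do **not** simulate gel smearing or band-shape artifacts, sequence
or pH dependence, temperature, or systematic densitometry bias. Passing
round-trip tests therefore demonstrates correctness of the estimation
machinery under the model's own noise assumptions, not robustness to
every failure mode of real gels.

Determinism: each design seed is split with `SeedSequence.spawn`, one
child per replicate, so replicates are statistically independent yet the
whole table is reproducible from one integer.

## Pipeline

`run()` executes a YAML/JSON config: per experiment it generates or reads
band tables, normalizes, fits per the recipe (`kobs`, `k1`, `hydrolysis`,
`ligation`), optionally propagates Monte Carlo uncertainty, and writes a
rate-constant table, a half-life table (cells formatted value(sd) with a
one-significant-digit uncertainty, e.g. `72(2)`), and a fold-change
report. Fold uncertainties use the first-order delta method assuming
independent estimates — an explicit, documented choice, since fold
contrasts are usually quoted without uncertainty. Replicate-level k_obs
fits are summarized as mean ± sd across replicates (N = replicate count);
the nonlinear k1 fit pools replicates instead, which is the reading of
"fit to all the data" adopted here. Per-experiment failures are logged
and reported without aborting the remaining experiments, and rerunning
the same config and seed reproduces byte-identical tables.

## Problem sizes and numerical choices

Round-trip and acceptance computations use 7-point extension time courses
on 0.05–1 h, 6-point hydrolysis courses on 0–96 h, and 8–11-point decay
grids, in triplicate — grids representative of the gel experiments they
emulate, where each point is one lane. The parameter-recovery test grid
spans k1 ∈ {0.1, 1, 12}, k2 ∈ {0.2, 0.7}, k3 ∈ {0.05, 0.118, 9} h⁻¹ and
p_gly0 ∈ {0.26, 0.45, 0.60}, with the time window scaled to ~4/(k1+k2) so
every combination is informative. Optimizer tolerances are 1e-14
(xtol/ftol/gtol) — negligible cost for one parameter, and tight enough
that noiseless round trips recover rates to 1e-4 relative or better. A
fitted k1 below 1e-6 h⁻¹ is reported as "at the zero bound": rates that
small are unresolvable in these assays.

## Known limitations

- The 2′- and 3′-aminoacyl regioisomers interconvert rapidly by
  transacylation and are treated as one species; fitted rates combine
  reactions initiated from both.
- Reactions are modeled as irreversible and strictly pseudo-first-order;
  substrate depletion, reversible binding and sequence context are out of
  scope, and Mg²⁺ enters only as a discrete condition label.
- k2 and k3 are fixed inputs, never co-fit with k1; correlated errors
  among them are only captured to the extent the Monte Carlo spec encodes
  them (draws are independent).
- The noise model's magnitudes are configuration knobs, not estimates of
  any particular instrument's error.
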