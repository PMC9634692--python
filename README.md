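# glykin

Kinetic analysis of non-enzymatic RNA primer extension and ligation from
2′(3′)-aminoacylated primers.

Amino acids esterified to the 2′(3′)-OH of an RNA primer can attack an
activated 5′-phosphate with their α-amine, extending the primer through a
phosphoramidate (N–P) bridge instead of the canonical phosphodiester. For
researchers studying prebiotic RNA copying chemistry, the central
quantitative questions are how fast this aminoacyl pathway runs compared
with canonical extension, how it competes with hydrolysis of the labile
aminoacyl ester, and how stable the resulting amino-acid-bridged RNA is.
`glykin` packages the full analysis: the kinetic model, estimators for
its rate constants from gel densitometry time courses, Monte Carlo
uncertainty propagation, and a synthetic-data generator so everything is
testable without experimental data.

## The model

A primer pool starts as a fraction `p_gly0` aminoacylated primer (P_gly)
and `1 − p_gly0` native RNA (P_rna). Under pseudo-first-order conditions
three irreversible reactions compete — extension of the acylated primer
(k1, giving the NP+1 product), ester hydrolysis (k2, returning native
primer), and native extension (k3, giving the OP+1 product):

```
dP_gly/dt = −(k1+k2)·P_gly        P_gly(t)   = p_gly0·e^{−(k1+k2)t}
dP_gly+1/dt = k1·P_gly            P_gly+1(t) = p_gly0·k1/(k1+k2)·(1−e^{−(k1+k2)t})
dP_rna/dt = k2·P_gly − k3·P_rna   P_rna(t)   = closed form (see docs/methods.md)
dP_rna1/dt = k3·P_rna             P_rna+1(t) = 1 − the rest
```

Simple first-order observables (native extension, ligation controls,
hydrolysis) are fit log-linearly: `k_obs` is the slope of `−ln(P/P0)`
versus time, and half-lives are `ln 2 / k_obs`. The aminoacyl rate `k1`
is fit by bounded nonlinear least squares of the closed-form solutions
against the total-primer and product bands, with `k2`, `k3` and `p_gly0`
fixed from independent measurements; its uncertainty is propagated by
refitting under truncated-normal draws of those fixed inputs.

## Worked example

Simulate a triplicate extension experiment at 0 mM Mg²⁺ with 5% band
noise, normalize the lanes, and recover `k1`:

```python
import glykin as g

design = g.ExperimentDesign(
    experiment_type="extension", condition="gly 0 mM Mg",
    rates=g.RateConstants(k1=12.0, k2=0.7, k3=0.118),
    times=[0.05, 0.1, 0.2, 0.33, 0.5, 0.75, 1.0],
    p_gly0=0.4, n_replicates=3,
    noise=g.NoiseModel(sd_multiplicative=0.05), seed=20,
)
table, manifest = g.gen_extension_experiment(design)
print(table.head(3).to_string(index=False))
#   condition replicate  time_h   band   intensity
# gly 0 mM Mg      rep1    0.05 primer 7932.018104
# gly 0 mM Mg      rep1    0.05    np1 1666.361648
# gly 0 mM Mg      rep1    0.05    op1   34.737992

tcs = list(g.to_timecourse(table, g.BandMap.extension()).values())
fit = g.fit_k1(tcs, k2=0.7, k3=0.118, p_gly0=0.4)
print("k1 =", round(fit.k1, 2))
# k1 = 12.78

spec = g.UncertaintySpec(p_gly0=(0.4, 0.02), k2=(0.7, 0.05),
                         k3=(0.118, 0.01), n_draws=1000, seed=20)
mc = g.mc_propagate(tcs, spec)
print(f"k1 = {mc.k1:.1f} +/- {mc.sd:.1f} (16-84%: {mc.q16:.1f}-{mc.q84:.1f})")
# k1 = 12.8 +/- 1.8 (16-84%: 11.2-14.7)

print("fold vs RNA:", round(g.fold_change(mc.k1, 0.118), 1))
# fold vs RNA: 108.6
```

The raw intensities carry lane-to-lane loading variation and band noise;
lane normalization removes the former, and the fitted `k1` lands within
the noise of the generating value 12.0 h⁻¹ — roughly two orders of
magnitude above the canonical RNA extension rate at the same condition.

There is also a CLI over the same machinery (`glykin simulate | fit |
report | run-all`), driven by a YAML/JSON config listing experiments,
fit recipes and Monte Carlo settings; see `glykin run-all --help`.

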