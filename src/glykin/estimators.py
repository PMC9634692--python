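"""Rate-constant estimators for gel-band time courses.

Three scikit-learn style estimators carry the fitting logic:

* :class:`LogLinearRateEstimator` — the observed pseudo-first-order rate
  constant ``k_obs`` as the slope of an ordinary least-squares fit of
  ``-ln(P/P0)`` against time (free intercept, reported for diagnostics).
* :class:`AminoacylRateEstimator` — the aminoacyl-extension rate ``k1``
  by bounded nonlinear least squares of the closed-form competing-pathway
  solutions against the observed total-primer and product bands, with
  ``k2``, ``k3`` and ``p_gly0`` fixed from independent measurements.
* :class:`MonteCarloK1` — uncertainty on ``k1`` propagated from the
  uncertainties of the fixed inputs by refitting under truncated-normal
  draws of ``(p_gly0, k2, k3)``.

The module-level functions (:func:`fit_kobs`, :func:`fit_k1`,
:func:`mc_propagate`, :func:`half_life`, :func:`censor_ligation`,
:func:`fold_change`) are thin wrappers returning frozen result records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .errors import (
    ComputationError,
    DataError,
    InputDomainError,
    InsufficientDataError,
)
from .model import InitialComposition, RateConstants, _fractions

__all__ = [
    "ObservedTimeCourse",
    "KObsFit",
    "K1Fit",
    "UncertaintySpec",
    "LogLinearRateEstimator",
    "AminoacylRateEstimator",
    "MonteCarloK1",
    "fit_kobs",
    "half_life",
    "fit_k1",
    "mc_propagate",
    "censor_ligation",
    "fold_change",
]

logger = logging.getLogger(__name__)

#: observable names an ObservedTimeCourse may carry
OBSERVABLES = ("primer", "np1", "op1", "ligated", "primer_gly", "primer_rna")

_TIME_GRID_ATOL = 1e-6


@dataclass(frozen=True)
class ObservedTimeCourse:
    """Lane-normalized gel observables for one condition/replicate.

    ``observables`` maps names from :data:`OBSERVABLES` to fraction arrays
    aligned with ``t``; which names are present depends on the experiment
    type (extension gels resolve primer/np1/op1, acidic hydrolysis gels
    resolve primer_gly/primer_rna, ligation gels give primer/ligated).
    """

    condition: str
    replicate: str
    t: np.ndarray
    observables: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        if t.ndim != 1 or t.size == 0:
            raise DataError("time grid must be a nonempty 1-D array")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise DataError("times must be >= 0 and strictly increasing")
        obs = {}
        for name, values in dict(self.observables).items():
            if name not in OBSERVABLES:
                raise DataError(f"unknown observable {name!r}")
            v = np.asarray(values, dtype=float)
            if v.shape != t.shape:
                raise DataError(
                    f"observable {name!r} has shape {v.shape}, "
                    f"expected {t.shape}"
                )
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-6):
                raise DataError(f"observable {name!r} outside [0, 1]")
            obs[name] = v
        if not obs:
            raise DataError("time course carries no observables")
        total = np.sum(list(obs.values()), axis=0)
        if np.any(total > 1 + 1e-6):
            raise DataError("observable fractions sum to more than 1")
        object.__setattr__(self, "observables", obs)

    def __len__(self) -> int:
        return int(self.t.size)

    def has(self, name: str) -> bool:
        return name in self.observables

    def subset(self, mask: np.ndarray) -> "ObservedTimeCourse":
        """Time course restricted to the points where ``mask`` is True."""
        return ObservedTimeCourse(
            condition=self.condition,
            replicate=self.replicate,
            t=self.t[mask],
            observables={k: v[mask] for k, v in self.observables.items()},
        )


@dataclass(frozen=True)
class KObsFit:
    """Result of a log-linear k_obs fit."""

    k_obs: float
    stderr: float
    intercept: float
    n_points: int
    rss: float
    condition: str = ""
    observable: str = "primer"


@dataclass(frozen=True)
class K1Fit:
    """Result of the nonlinear k1 fit, optionally with Monte Carlo spread.

    ``sd``, ``q16`` and ``q84`` are populated only by
    :func:`mc_propagate`; ``fixed`` records the (k2, k3, p_gly0) the fit
    conditioned on.
    """

    k1: float
    ssr: float
    converged: bool
    at_bound: bool
    n_points: int
    n_excluded: int
    fixed: dict = field(default_factory=dict)
    sd: float | None = None
    q16: float | None = None
    q84: float | None = None
    n_draws: int | None = None
    seed: int | None = None
    condition: str = ""
    method: str = "nonlinear_ls"


@dataclass(frozen=True)
class UncertaintySpec:
    """Means and standard deviations of the fixed inputs for Monte Carlo.

    Draws are normal, truncated at 0 (p_gly0 additionally at 1); a seed is
    mandatory so every summary is reproducible.
    """

    p_gly0: tuple[float, float]
    k2: tuple[float, float]
    k3: tuple[float, float]
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_gly0", "k2", "k3"):
            mean, sd = getattr(self, name)
            if sd < 0 or not math.isfinite(sd) or not math.isfinite(mean):
                raise InputDomainError(
                    f"{name}=(mean={mean!r}, sd={sd!r}) invalid: sd must be "
                    "finite and >= 0"
                )
        if self.n_draws < 1:
            raise InputDomainError("n_draws must be >= 1")


class LogLinearRateEstimator(BaseEstimator):
    """Observed first-order rate constant from a decaying band fraction.

    Fits ``-ln(P/P0) = k_obs * t + b`` by ordinary least squares, where
    ``P0`` is the fraction at the first time point.  The free intercept
    absorbs small normalization offsets at t = 0 and is reported as a
    diagnostic.

    Attributes (after ``fit``)
    --------------------------
    k_obs_ : float
        Fitted slope, per hour.
    k_obs_stderr_ : float
        Standard error of the slope (NaN with exactly 2 points).
    intercept_ : float
        Fitted intercept on the -ln(P/P0) scale.
    n_points_ : int
        Number of points used.
    rss_ : float
        Residual sum of squares on the -ln scale.
    """

    def fit(self, t, p) -> "LogLinearRateEstimator":
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise DataError("t and p must be 1-D arrays of equal length")
        bad = ~(p > 0)
        if np.any(bad):
            raise DataError(
                "non-positive band fractions at t = "
                f"{t[bad].tolist()}; cannot take logarithms"
            )
        if t.size < 2:
            raise InsufficientDataError(
                f"need >= 2 usable points, got {t.size}"
            )
        y = -np.log(p / p[0])
        res = stats.linregress(t, y)
        self.k_obs_ = float(res.slope)
        self.k_obs_stderr_ = float(res.stderr)
        self.intercept_ = float(res.intercept)
        self.n_points_ = int(t.size)
        resid = y - (res.slope * t + res.intercept)
        self.rss_ = float(np.dot(resid, resid))
        return self

    def predict(self, t) -> np.ndarray:
        """Predicted P/P0 at times ``t`` under the fitted line."""
        t = np.asarray(t, dtype=float)
        return np.exp(-(self.k_obs_ * t + self.intercept_))


class AminoacylRateEstimator(BaseEstimator):
    """Nonlinear least-squares estimator of the aminoacyl extension rate k1.

    With ``k2`` (ester hydrolysis), ``k3`` (native-primer extension) and
    ``p_gly0`` (initial acylated fraction) fixed from independent
    measurements, minimizes the unweighted sum of squared residuals of the
    closed-form model against the observed bands, pooled over all points
    and replicates, over the single bounded parameter ``k1 in [0, k1_max]``:

    * ``primer``  vs model ``P_gly + P_rna`` (the co-migrating band);
    * ``np1``     vs model ``P_gly+1`` when the product bands are resolved;
    * ``ligated`` vs model ``P_gly+1 + P_rna+1`` when they are not.

    The optimizer is restarted from {0.1x, 1x, 10x} a slope-based initial
    guess (multi-start removes local-minimum risk for the 1-D objective);
    points with non-positive primer fraction are excluded with a logged
    warning and counted in ``n_excluded_``.

    Attributes (after ``fit``)
    --------------------------
    k1_ : float
        Fitted rate, per hour.
    ssr_ : float
        Sum of squared residuals at the minimum.
    converged_ : bool
        True if at least one optimizer start converged.
    at_bound_ : bool
        True if the minimizer lies on the 0 or ``k1_max`` boundary.
    n_points_, n_excluded_ : int
    """

    def __init__(
        self,
        k2: float = 0.0,
        k3: float = 0.0,
        p_gly0: float = 0.5,
        k1_max: float = 1e4,
        n_starts: int = 3,
        k1_init: float | None = None,
    ):
        self.k2 = k2
        self.k3 = k3
        self.p_gly0 = p_gly0
        self.k1_max = k1_max
        self.n_starts = n_starts
        self.k1_init = k1_init

    def _residuals(
        self, k1, blocks: list[tuple[np.ndarray, np.ndarray, str]]
    ) -> np.ndarray:
        rates = RateConstants(k1=float(np.asarray(k1).reshape(())),
                              k2=self.k2, k3=self.k3)
        init = InitialComposition(p_gly0=self.p_gly0)
        out = []
        for t, observed, kind in blocks:
            p_gly, p_rna, p_gly1, p_rna1 = _fractions(rates, init, t)
            if kind == "primer":
                model = p_gly + p_rna
            elif kind == "np1":
                model = p_gly1
            else:  # ligated: unresolved NP+1 / OP+1 band
                model = p_gly1 + p_rna1
            out.append(model - observed)
        return np.concatenate(out)

    def fit(
        self, timecourses: ObservedTimeCourse | Sequence[ObservedTimeCourse]
    ) -> "AminoacylRateEstimator":
        if isinstance(timecourses, ObservedTimeCourse):
            timecourses = [timecourses]
        if not timecourses:
            raise InsufficientDataError("no time courses to fit")
        if self.k2 < 0 or self.k3 < 0:
            raise InputDomainError("k2 and k3 must be >= 0")
        if not (0.0 <= self.p_gly0 <= 1.0):
            raise InputDomainError("p_gly0 must lie in [0, 1]")

        blocks: list[tuple[np.ndarray, np.ndarray, str]] = []
        n_points = 0
        n_excluded = 0
        for tc in timecourses:
            if not tc.has("primer"):
                raise DataError(
                    f"time course {tc.condition!r}/{tc.replicate!r} lacks a "
                    "primer observable"
                )
            product = "np1" if tc.has("np1") else "ligated"
            if not tc.has(product):
                raise DataError(
                    f"time course {tc.condition!r}/{tc.replicate!r} lacks a "
                    "product observable (np1 or ligated)"
                )
            keep = tc.observables["primer"] > 0
            if not np.all(keep):
                dropped = tc.t[~keep].tolist()
                n_excluded += int(np.sum(~keep))
                logger.warning(
                    "excluding %d point(s) with non-positive primer fraction "
                    "at t=%s in %s/%s",
                    int(np.sum(~keep)),
                    dropped,
                    tc.condition,
                    tc.replicate,
                )
            if np.sum(keep) == 0:
                continue
            t = tc.t[keep]
            blocks.append((t, tc.observables["primer"][keep], "primer"))
            blocks.append((t, tc.observables[product][keep], product))
            n_points += int(np.sum(keep))
        if n_points < 2:
            raise InsufficientDataError(
                f"only {n_points} usable point(s) across all time courses"
            )

        guess = self.k1_init if self.k1_init is not None else self._guess(blocks)
        guess = float(np.clip(guess, 1e-6, self.k1_max))
        starts = [guess] if self.n_starts == 1 else [
            s * guess for s in (0.1, 1.0, 10.0)[: self.n_starts]
        ]

        best = None
        any_success = False
        for x0 in starts:
            x0 = float(np.clip(x0, 0.0, self.k1_max))
            res = optimize.least_squares(
                self._residuals,
                x0=[x0],
                bounds=([0.0], [self.k1_max]),
                args=(blocks,),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            any_success = any_success or res.success
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            self.k1_ = float("nan")
            self.ssr_ = float("nan")
            self.converged_ = False
            self.at_bound_ = False
        else:
            self.k1_ = float(best.x[0])
            self.ssr_ = float(2.0 * best.cost)
            self.converged_ = True
            # 1e-6 h^-1 is far below any resolvable rate in these assays
            self.at_bound_ = bool(
                self.k1_ <= 1e-6 or self.k1_ >= self.k1_max * (1 - 1e-9)
            )
        self.n_points_ = n_points
        self.n_excluded_ = n_excluded
        return self

    def _guess(self, blocks) -> float:
        """Slope-based initial guess: k_obs of the pooled primer decay."""
        ts, ps = [], []
        for t, observed, kind in blocks:
            if kind == "primer":
                ts.append(t)
                ps.append(observed)
        t = np.concatenate(ts)
        p = np.concatenate(ps)
        try:
            slope = stats.linregress(t, -np.log(p / np.max(p))).slope
        except Exception:
            return 1.0
        return max(float(slope), 1e-3)

    def predict(self, t) -> dict[str, np.ndarray]:
        """Model observables at times ``t`` under the fitted k1."""
        t = np.asarray(t, dtype=float)
        rates = RateConstants(k1=self.k1_, k2=self.k2, k3=self.k3)
        init = InitialComposition(p_gly0=self.p_gly0)
        p_gly, p_rna, p_gly1, p_rna1 = _fractions(rates, init, t)
        return {
            "primer": p_gly + p_rna,
            "np1": p_gly1,
            "op1": p_rna1,
            "ligated": p_gly1 + p_rna1,
        }


class MonteCarloK1(BaseEstimator):
    """Monte Carlo propagation of fixed-input uncertainty into k1.

    For each draw, (p_gly0, k2, k3) are sampled from normal distributions
    truncated at 0 (p_gly0 also at 1) and k1 is refit; the summary is the
    median estimate, the standard deviation across draws, and the 16th/84th
    percentiles.  Reproducible under ``spec.seed``.
    """

    def __init__(self, spec: UncertaintySpec, k1_max: float = 1e4):
        self.spec = spec
        self.k1_max = k1_max

    @staticmethod
    def _draw(rng: np.random.Generator, mean: float, sd: float,
              upper: float = np.inf) -> float:
        if sd == 0:
            return mean
        a = (0.0 - mean) / sd
        b = (upper - mean) / sd
        return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                         random_state=rng))

    def fit(
        self, timecourses: ObservedTimeCourse | Sequence[ObservedTimeCourse]
    ) -> "MonteCarloK1":
        spec = self.spec
        base = AminoacylRateEstimator(
            k2=spec.k2[0], k3=spec.k3[0], p_gly0=spec.p_gly0[0],
            k1_max=self.k1_max,
        ).fit(timecourses)
        rng = np.random.default_rng(spec.seed)
        draws = np.empty(spec.n_draws)
        failures = 0
        for i in range(spec.n_draws):
            p0 = self._draw(rng, *spec.p_gly0, upper=1.0)
            k2 = self._draw(rng, *spec.k2)
            k3 = self._draw(rng, *spec.k3)
            est = AminoacylRateEstimator(
                k2=k2, k3=k3, p_gly0=p0, k1_max=self.k1_max,
                n_starts=1, k1_init=max(base.k1_, 1e-3),
            ).fit(timecourses)
            if est.converged_:
                draws[i] = est.k1_
            else:
                draws[i] = np.nan
                failures += 1
        if failures > 0.2 * spec.n_draws:
            raise ComputationError(
                f"{failures}/{spec.n_draws} Monte Carlo refits failed to "
                "converge; uncertainty summary would be unreliable"
            )
        good = draws[~np.isnan(draws)]
        self.base_ = base
        self.k1_ = float(np.median(good))
        self.sd_ = float(np.std(good, ddof=1)) if good.size > 1 else 0.0
        self.q16_, self.q84_ = (
            float(np.percentile(good, 16)),
            float(np.percentile(good, 84)),
        )
        self.n_failures_ = failures
        return self


def fit_kobs(
    tc: ObservedTimeCourse, observable: str = "primer"
) -> KObsFit:
    """Log-linear k_obs fit of one observable of a time course."""
    if not tc.has(observable):
        raise DataError(
            f"time course {tc.condition!r}/{tc.replicate!r} has no "
            f"observable {observable!r}"
        )
    est = LogLinearRateEstimator().fit(tc.t, tc.observables[observable])
    return KObsFit(
        k_obs=est.k_obs_,
        stderr=est.k_obs_stderr_,
        intercept=est.intercept_,
        n_points=est.n_points_,
        rss=est.rss_,
        condition=tc.condition,
        observable=observable,
    )


def half_life(k_obs: float) -> float:
    """First-order half-life ln(2)/k_obs, hours."""
    if not (k_obs > 0) or not math.isfinite(k_obs):
        raise InputDomainError(
            f"half-life requires k_obs > 0, got {k_obs!r}"
        )
    return math.log(2) / k_obs


def fit_k1(
    tc: ObservedTimeCourse | Sequence[ObservedTimeCourse],
    k2: float,
    k3: float,
    p_gly0: float,
) -> K1Fit:
    """Nonlinear k1 fit with (k2, k3, p_gly0) fixed; see
    :class:`AminoacylRateEstimator`."""
    est = AminoacylRateEstimator(k2=k2, k3=k3, p_gly0=p_gly0).fit(tc)
    first = tc if isinstance(tc, ObservedTimeCourse) else tc[0]
    return K1Fit(
        k1=est.k1_,
        ssr=est.ssr_,
        converged=est.converged_,
        at_bound=est.at_bound_,
        n_points=est.n_points_,
        n_excluded=est.n_excluded_,
        fixed={"k2": k2, "k3": k3, "p_gly0": p_gly0},
        condition=first.condition,
    )


def mc_propagate(
    tc: ObservedTimeCourse | Sequence[ObservedTimeCourse],
    spec: UncertaintySpec,
) -> K1Fit:
    """Monte Carlo uncertainty on k1; see :class:`MonteCarloK1`."""
    mc = MonteCarloK1(spec).fit(tc)
    first = tc if isinstance(tc, ObservedTimeCourse) else tc[0]
    return K1Fit(
        k1=mc.k1_,
        ssr=mc.base_.ssr_,
        converged=mc.base_.converged_,
        at_bound=mc.base_.at_bound_,
        n_points=mc.base_.n_points_,
        n_excluded=mc.base_.n_excluded_,
        fixed={
            "k2": spec.k2,
            "k3": spec.k3,
            "p_gly0": spec.p_gly0,
        },
        sd=mc.sd_,
        q16=mc.q16_,
        q84=mc.q84_,
        n_draws=spec.n_draws,
        seed=spec.seed,
        condition=first.condition,
        method="nonlinear_ls+monte_carlo",
    )


def censor_ligation(
    tc_amino: ObservedTimeCourse,
    tc_rna_control: ObservedTimeCourse,
    threshold: float = 0.02,
) -> ObservedTimeCourse:
    """Restrict a ligation time course to points where the pure-RNA control
    produced less than ``threshold`` ligated product.

    The unresolved ligation band is attributable to the aminoacyl pathway
    only while the control's contribution is negligible; the default 2%
    cut implements that rule.
    """
    if not tc_rna_control.has("ligated"):
        raise DataError("control time course has no ligated observable")
    if tc_amino.t.shape != tc_rna_control.t.shape or not np.allclose(
        tc_amino.t, tc_rna_control.t, rtol=0, atol=_TIME_GRID_ATOL
    ):
        raise DataError(
            "aminoacyl and control time courses are not on the same time grid"
        )
    mask = tc_rna_control.observables["ligated"] < threshold
    if not np.any(mask):
        raise InsufficientDataError(
            f"no time points where the RNA control's ligated fraction is "
            f"below {threshold}"
        )
    return tc_amino.subset(mask)


def fold_change(k_a: float, k_b: float) -> float:
    """Ratio k_a / k_b of two rate constants."""
    if not (k_b > 0):
        raise InputDomainError(f"denominator rate must be > 0, got {k_b!r}")
    return k_a / k_b
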