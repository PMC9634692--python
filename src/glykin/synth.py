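"""Synthetic gel-band time courses with known ground truth.

Emulates the statistical structure of densitometry data from the
non-enzymatic extension/ligation assays: incomplete primer acylation
(yields drawn in the 26–60% range when not specified), co-migration of
acylated and native primer on standard gels, resolved NP+1/OP+1 product
bands, a single unresolved ligation band, acidic-gel hydrolysis
experiments where the two primer forms do resolve, per-lane loading
variability, and multiplicative noise on band intensities.  Every
generator returns a lane table in the exact schema :mod:`glykin.gel`
reads, plus a JSON-serializable manifest recording the true parameters
and seeds, so estimators can be tested by round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputDomainError
from .gel import LANE_COLUMNS
from .model import InitialComposition, RateConstants, simulate_trajectory

__all__ = [
    "ACYLATION_YIELD_RANGE",
    "NoiseModel",
    "ExperimentDesign",
    "gen_extension_experiment",
    "gen_hydrolysis_experiment",
    "gen_ligation_experiment",
    "gen_condition_panel",
]

#: range of Flexizyme acylation yields observed across preparations
ACYLATION_YIELD_RANGE = (0.26, 0.60)

EXPERIMENT_TYPES = ("extension", "hydrolysis_acidic", "ligation", "no_template")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise on raw band intensities.

    sd_multiplicative
        Standard deviation of the lognormal factor applied to each band
        (densitometry error scales with band size); 0 disables it.
    baseline
        Optional additive background, as a fraction of the lane loading
        total, added to every band.
    """

    sd_multiplicative: float = 0.05
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_multiplicative < 0 or self.baseline < 0:
            raise InputDomainError("noise parameters must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Full specification of one synthetic experiment.

    ``p_gly0=None`` draws the acylation yield uniformly from
    :data:`ACYLATION_YIELD_RANGE` (one draw shared by all replicates, as
    technical replicates share the acylation prep).  ``lane_total`` is the
    mean loading per lane in arbitrary densitometry units;
    ``lane_total_sd`` the lognormal spread that models pipetting/loading
    variability and makes lane normalization non-trivial.
    """

    experiment_type: str
    condition: str
    rates: RateConstants
    times: Sequence[float]
    p_gly0: float | None = None
    n_replicates: int = 3
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    lane_total: float = 1e4
    lane_total_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.experiment_type not in EXPERIMENT_TYPES:
            raise InputDomainError(
                f"unknown experiment type {self.experiment_type!r}"
            )
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise InputDomainError(
                "times must be nonempty, >= 0 and strictly increasing"
            )
        if self.n_replicates < 1:
            raise InputDomainError("n_replicates must be >= 1")
        if self.p_gly0 is not None and not (0 <= self.p_gly0 <= 1):
            raise InputDomainError("p_gly0 must lie in [0, 1]")


def _resolve_p_gly0(design: ExperimentDesign,
                    rng: np.random.Generator) -> float:
    if design.p_gly0 is not None:
        return float(design.p_gly0)
    lo, hi = ACYLATION_YIELD_RANGE
    return float(rng.uniform(lo, hi))


def _emit_lanes(
    design: ExperimentDesign,
    condition: str,
    times: np.ndarray,
    band_fractions: dict[str, np.ndarray],
    seed_seq: np.random.SeedSequence,
) -> pd.DataFrame:
    """Turn true band fractions into noisy raw-intensity lane rows.

    Each replicate gets its own child seed, so replicates are independent
    but the whole table is reproducible from the design seed.
    """
    rows = []
    children = seed_seq.spawn(design.n_replicates)
    for rep, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        for i, t in enumerate(times):
            total = design.lane_total * rng.lognormal(
                0.0, design.lane_total_sd
            )
            for band, fracs in band_fractions.items():
                noise = rng.lognormal(0.0, design.noise.sd_multiplicative)
                intensity = fracs[i] * total * noise
                intensity += design.noise.baseline * total
                rows.append(
                    (condition, f"rep{rep}", float(t), band, intensity)
                )
    return pd.DataFrame(rows, columns=list(LANE_COLUMNS))


def _manifest(design: ExperimentDesign, p_gly0: float, **extra) -> dict:
    m = {
        "experiment_type": design.experiment_type,
        "condition": design.condition,
        "k1": design.rates.k1,
        "k2": design.rates.k2,
        "k3": design.rates.k3,
        "p_gly0": p_gly0,
        "times": [float(t) for t in design.times],
        "n_replicates": design.n_replicates,
        "noise_sd_multiplicative": design.noise.sd_multiplicative,
        "noise_baseline": design.noise.baseline,
        "lane_total": design.lane_total,
        "lane_total_sd": design.lane_total_sd,
        "seed": design.seed,
    }
    m.update(extra)
    return m


def gen_extension_experiment(
    design: ExperimentDesign,
) -> tuple[pd.DataFrame, dict]:
    """Primer-extension experiment on a standard denaturing gel.

    Bands: ``primer`` (aminoacylated + native primer, co-migrating),
    ``np1`` (phosphoramidate +1 product), ``op1`` (phosphodiester +1
    product).  True fractions follow the closed-form model.
    """
    if design.experiment_type not in ("extension", "no_template"):
        raise InputDomainError(
            f"expected an extension design, got {design.experiment_type!r}"
        )
    seed_seq = np.random.SeedSequence(design.seed)
    p0_seq, lane_seq = seed_seq.spawn(2)
    p_gly0 = _resolve_p_gly0(design, np.random.default_rng(p0_seq))
    times = np.asarray(design.times, dtype=float)
    traj = simulate_trajectory(
        design.rates, InitialComposition(p_gly0), times
    )
    bands = {
        "primer": traj.fractions("p_gly") + traj.fractions("p_rna"),
        "np1": traj.fractions("p_gly1"),
        "op1": traj.fractions("p_rna1"),
    }
    table = _emit_lanes(design, design.condition, times, bands, lane_seq)
    return table, _manifest(design, p_gly0)


def gen_hydrolysis_experiment(
    design: ExperimentDesign,
) -> tuple[pd.DataFrame, dict]:
    """Aminoacyl-ester hydrolysis on an acidic gel (no activated substrate).

    The acylated and native primer resolve into separate bands;
    ``primer_gly`` decays at k2 and ``primer_rna`` gains the lost mass.
    k1 and k3 must be 0: there is nothing to extend with.
    """
    if design.experiment_type != "hydrolysis_acidic":
        raise InputDomainError(
            f"expected a hydrolysis_acidic design, got "
            f"{design.experiment_type!r}"
        )
    if design.rates.k1 != 0 or design.rates.k3 != 0:
        raise InputDomainError(
            "hydrolysis experiments have no activated substrate: "
            "k1 and k3 must be 0"
        )
    seed_seq = np.random.SeedSequence(design.seed)
    p0_seq, lane_seq = seed_seq.spawn(2)
    p_gly0 = _resolve_p_gly0(design, np.random.default_rng(p0_seq))
    times = np.asarray(design.times, dtype=float)
    traj = simulate_trajectory(
        design.rates, InitialComposition(p_gly0), times
    )
    bands = {
        "primer_gly": traj.fractions("p_gly"),
        "primer_rna": traj.fractions("p_rna"),
    }
    table = _emit_lanes(design, design.condition, times, bands, lane_seq)
    return table, _manifest(design, p_gly0)


def gen_ligation_experiment(
    design: ExperimentDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Three-arm ligation experiment.

    Returns (aminoacyl arm, RNA-control arm, hydrolysis arm, manifest):

    * aminoacyl arm — evolves under (k1 = aminoacyl ligation rate, k2,
      k3 = native-RNA ligation rate); the single ``ligated`` band is the
      unresolved sum of the NP and OP ligation products;
    * control arm — pure RNA primer (p_gly0 = 0) with the same k3, used
      for the censoring rule and the k3 estimate;
    * hydrolysis arm — acidic-gel decay of the acylated primer at k2,
      used for the k2 estimate.
    """
    if design.experiment_type != "ligation":
        raise InputDomainError(
            f"expected a ligation design, got {design.experiment_type!r}"
        )
    seed_seq = np.random.SeedSequence(design.seed)
    p0_seq, amino_seq, ctrl_seq, hyd_seq = seed_seq.spawn(4)
    p_gly0 = _resolve_p_gly0(design, np.random.default_rng(p0_seq))
    times = np.asarray(design.times, dtype=float)

    traj = simulate_trajectory(
        design.rates, InitialComposition(p_gly0), times
    )
    amino_bands = {
        "primer": traj.fractions("p_gly") + traj.fractions("p_rna"),
        "ligated": traj.fractions("p_gly1") + traj.fractions("p_rna1"),
    }
    amino = _emit_lanes(
        design, design.condition, times, amino_bands, amino_seq
    )

    ctrl_rates = RateConstants(k1=0.0, k2=0.0, k3=design.rates.k3)
    ctrl_traj = simulate_trajectory(
        ctrl_rates, InitialComposition(0.0), times
    )
    ctrl_bands = {
        "primer": ctrl_traj.fractions("p_rna"),
        "ligated": ctrl_traj.fractions("p_rna1"),
    }
    control = _emit_lanes(
        design, f"{design.condition}__rna_control", times, ctrl_bands,
        ctrl_seq,
    )

    hyd_rates = RateConstants(k1=0.0, k2=design.rates.k2, k3=0.0)
    hyd_traj = simulate_trajectory(
        hyd_rates, InitialComposition(p_gly0), times
    )
    hyd_bands = {
        "primer_gly": hyd_traj.fractions("p_gly"),
        "primer_rna": hyd_traj.fractions("p_rna"),
    }
    hydrolysis = _emit_lanes(
        design, f"{design.condition}__hydrolysis", times, hyd_bands, hyd_seq
    )
    manifest = _manifest(
        design,
        p_gly0,
        arms={
            "aminoacyl": design.condition,
            "rna_control": f"{design.condition}__rna_control",
            "hydrolysis": f"{design.condition}__hydrolysis",
        },
    )
    return amino, control, hydrolysis, manifest


def gen_condition_panel(
    designs: Sequence[ExperimentDesign],
) -> tuple[pd.DataFrame, list[dict]]:
    """Concatenated lane table across several single-table designs.

    Mirrors a condition series (e.g. an Mg2+ titration or an amino acid
    panel) as distinct condition labels in one table.
    """
    if not designs:
        raise InputDomainError("empty design list")
    labels = [d.condition for d in designs]
    if len(set(labels)) != len(labels):
        raise InputDomainError(f"duplicate condition labels in {labels}")
    tables = []
    manifests = []
    for design in designs:
        if design.experiment_type in ("extension", "no_template"):
            table, manifest = gen_extension_experiment(design)
        elif design.experiment_type == "hydrolysis_acidic":
            table, manifest = gen_hydrolysis_experiment(design)
        else:
            raise InputDomainError(
                "condition panels combine single-table designs "
                f"(extension or hydrolysis), got {design.experiment_type!r}"
            )
        tables.append(table)
        manifests.append(manifest)
    return pd.concat(tables, ignore_index=True), manifests
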