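"""Shared fixtures: canonical designs and noiseless synthetic experiments."""

import math

import numpy as np
import pytest

from glykin import (
    BandMap,
    ExperimentDesign,
    InitialComposition,
    NoiseModel,
    ObservedTimeCourse,
    RateConstants,
    simulate_trajectory,
    to_timecourse,
)

NO_NOISE = NoiseModel(sd_multiplicative=0.0, baseline=0.0)

# rate constants of the 0 mM Mg2+ extension comparison
K1_ZERO_MG = 12.0
K3_ZERO_MG = 0.118
K2_DEFAULT = 0.7

# observed ligation rates of the activation-group comparison
KOBS_2MEI = 1.81
KOBS_2AI = 0.281

# internal-linkage half-lives at 2.5 mM MgCl2 (hours)
HALF_LIFE_SS = 20.1
HALF_LIFE_DS = 72.0

EXTENSION_TIMES = (0.05, 0.1, 0.2, 0.33, 0.5, 0.75, 1.0)
HYDROLYSIS_TIMES = (0.0, 12.0, 24.0, 48.0, 72.0, 96.0)


def make_timecourse(rates, p_gly0, times, condition="test", replicate="rep1",
                    observables=("primer", "np1", "op1")):
    """Noise-free ObservedTimeCourse straight from the closed-form model."""
    traj = simulate_trajectory(rates, InitialComposition(p_gly0), times)
    available = {
        "primer": traj.fractions("p_gly") + traj.fractions("p_rna"),
        "np1": traj.fractions("p_gly1"),
        "op1": traj.fractions("p_rna1"),
        "ligated": traj.fractions("p_gly1") + traj.fractions("p_rna1"),
        "primer_gly": traj.fractions("p_gly"),
        "primer_rna": traj.fractions("p_rna"),
    }
    return ObservedTimeCourse(
        condition=condition,
        replicate=replicate,
        t=np.asarray(times, dtype=float),
        observables={k: available[k] for k in observables},
    )


@pytest.fixture
def extension_design():
    return ExperimentDesign(
        experiment_type="extension",
        condition="gly 0 mM Mg",
        rates=RateConstants(K1_ZERO_MG, K2_DEFAULT, K3_ZERO_MG),
        times=EXTENSION_TIMES,
        p_gly0=0.4,
        n_replicates=3,
        noise=NO_NOISE,
        seed=42,
    )


@pytest.fixture
def hydrolysis_design():
    return ExperimentDesign(
        experiment_type="hydrolysis_acidic",
        condition="ds internal 2.5 mM Mg",
        rates=RateConstants(0.0, math.log(2) / HALF_LIFE_DS, 0.0),
        times=HYDROLYSIS_TIMES,
        p_gly0=1.0,
        n_replicates=3,
        noise=NO_NOISE,
        seed=42,
    )


@pytest.fixture
def ligation_design():
    return ExperimentDesign(
        experiment_type="ligation",
        condition="gly 2MeI",
        rates=RateConstants(KOBS_2MEI, 0.3, 0.004),
        times=(0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
        p_gly0=0.5,
        n_replicates=3,
        noise=NO_NOISE,
        seed=42,
    )


def timecourses_from_table(table, experiment_type):
    """Lane-normalize a table and return replicate-sorted time courses."""
    tcs = to_timecourse(table, BandMap.for_type(experiment_type))
    return [tcs[key] for key in sorted(tcs)]
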