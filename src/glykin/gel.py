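"""Lane-table ingestion, lane normalization, and band-to-observable mapping.

Inputs begin at integrated band intensities as exported by densitometry
software: a delimited table with one row per (condition, replicate, time,
band).  Band intensity is normalized within each lane — each band divided
by the lane total — so species are expressed as fractions, and a
:class:`BandMap` states explicitly which gel bands contribute to which
model observable.  Co-migration is the central subtlety: on a standard
denaturing gel the aminoacylated and native primers run as one band
(``primer``), while the two +1 products resolve (``np1``, ``op1``); on an
acidic gel the two primer forms resolve (``primer_gly``, ``primer_rna``);
on a ligation gel the two ligation products collapse into one ``ligated``
band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .estimators import ObservedTimeCourse

__all__ = [
    "LANE_COLUMNS",
    "BandMap",
    "validate_lane_table",
    "normalize_lane",
    "to_timecourse",
    "read_band_table",
    "write_results",
]

#: required columns of a lane table, in canonical order
LANE_COLUMNS = ("condition", "replicate", "time_h", "band", "intensity")


@dataclass(frozen=True)
class BandMap:
    """Mapping from model observables to the gel bands that feed them.

    ``experiment_type`` tags which gel layout the map describes; the
    factory methods build the three canonical layouts.
    """

    experiment_type: str
    mapping: Mapping[str, tuple[str, ...]]

    @classmethod
    def extension(cls) -> "BandMap":
        """Standard denaturing gel: primers co-migrate, +1 products resolve."""
        return cls(
            experiment_type="extension",
            mapping={
                "primer": ("primer",),
                "np1": ("np1",),
                "op1": ("op1",),
            },
        )

    @classmethod
    def hydrolysis_acidic(cls) -> "BandMap":
        """Acidic gel: acylated and native primer run as separate bands."""
        return cls(
            experiment_type="hydrolysis_acidic",
            mapping={
                "primer_gly": ("primer_gly",),
                "primer_rna": ("primer_rna",),
            },
        )

    @classmethod
    def ligation(cls) -> "BandMap":
        """Ligation gel: single unresolved ligated-product band."""
        return cls(
            experiment_type="ligation",
            mapping={
                "primer": ("primer",),
                "ligated": ("ligated",),
            },
        )

    @classmethod
    def for_type(cls, experiment_type: str) -> "BandMap":
        factories = {
            "extension": cls.extension,
            "no_template": cls.extension,
            "hydrolysis_acidic": cls.hydrolysis_acidic,
            "ligation": cls.ligation,
        }
        if experiment_type not in factories:
            raise ConfigurationError(
                f"no band map for experiment type {experiment_type!r}"
            )
        return factories[experiment_type]()

    def band_to_observable(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for observable, bands in self.mapping.items():
            for band in bands:
                if band in out:
                    raise ConfigurationError(
                        f"band {band!r} claimed by both {out[band]!r} and "
                        f"{observable!r}"
                    )
                out[band] = observable
        return out


def validate_lane_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a lane table; returns it with canonical dtypes."""
    missing = [c for c in LANE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"lane table missing column(s) {missing}")
    out = table.loc[:, list(LANE_COLUMNS)].copy()
    for col in ("time_h", "intensity"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[out[col].isna()]
        if len(bad):
            raise DataError(
                f"non-numeric {col!r} value(s) at row(s) {bad.tolist()}"
            )
    if (out["intensity"] < 0).any():
        rows = out.index[out["intensity"] < 0].tolist()
        raise DataError(f"negative intensity at row(s) {rows}")
    if (out["time_h"] < 0).any():
        rows = out.index[out["time_h"] < 0].tolist()
        raise DataError(f"negative time at row(s) {rows}")
    key = ["condition", "replicate", "time_h", "band"]
    dup = out.duplicated(subset=key)
    if dup.any():
        raise DataError(
            "duplicate (condition, replicate, time, band) row(s): "
            f"{out.loc[dup, key].to_dict('records')}"
        )
    out["condition"] = out["condition"].astype(str)
    out["replicate"] = out["replicate"].astype(str)
    out["band"] = out["band"].astype(str)
    return out


def normalize_lane(lane: pd.DataFrame) -> dict[str, float]:
    """Band fractions of one lane: intensity / lane total.

    ``lane`` holds the rows sharing one (condition, replicate, time).
    """
    total = float(lane["intensity"].sum())
    if total <= 0:
        ident = lane.iloc[0][["condition", "replicate", "time_h"]].tolist()
        raise DataError(f"all-zero lane {ident}: cannot normalize")
    return {
        str(row.band): float(row.intensity) / total
        for row in lane.itertuples()
    }


def to_timecourse(
    table: pd.DataFrame, band_map: BandMap
) -> dict[tuple[str, str], ObservedTimeCourse]:
    """Lane-normalize a table and aggregate bands into model observables.

    Returns one :class:`ObservedTimeCourse` per (condition, replicate),
    keyed by that pair, with times sorted ascending.
    """
    table = validate_lane_table(table)
    owner = band_map.band_to_observable()
    unmapped = sorted(set(table["band"]) - set(owner))
    if unmapped:
        raise ConfigurationError(
            f"band(s) {unmapped} not claimed by the band map "
            f"({band_map.experiment_type})"
        )
    out: dict[tuple[str, str], ObservedTimeCourse] = {}
    for (condition, replicate), group in table.groupby(
        ["condition", "replicate"], sort=True
    ):
        times = np.sort(group["time_h"].unique())
        fractions: dict[str, np.ndarray] = {
            obs: np.zeros(times.size) for obs in band_map.mapping
        }
        for i, t in enumerate(times):
            lane = group[group["time_h"] == t]
            for band, frac in normalize_lane(lane).items():
                fractions[owner[band]][i] += frac
        out[(condition, replicate)] = ObservedTimeCourse(
            condition=condition,
            replicate=replicate,
            t=times,
            observables=fractions,
        )
    return out


def read_band_table(path: str | Path) -> pd.DataFrame:
    """Read a comma-delimited lane table with strict schema validation."""
    path = Path(path)
    try:
        table = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed lane table {path}: {exc}") from exc
    return validate_lane_table(table)


def write_band_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a lane table in the canonical column order."""
    validate_lane_table(table).to_csv(path, index=False)


def write_results(path: str | Path, rows: Iterable[Mapping]) -> pd.DataFrame:
    """Write fit results, one row per fitted parameter.

    Each row supplies condition, parameter, estimate, sd, n_points,
    method and seed; missing fields are emitted empty.
    """
    columns = [
        "condition", "parameter", "estimate", "sd", "n_points", "method",
        "seed",
    ]
    frame = pd.DataFrame(list(rows))
    for col in columns:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame.loc[:, columns]
    frame.to_csv(path, index=False)
    return frame
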