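"""Readers and writers for the four demographic data streams.

All streams are plain CSV, year-aligned on a common calendar index:

``counts.csv``
    year, breeding_pairs
``productivity.csv``
    year, n_broods, n_fledglings
``recoveries.csv``
    year, n_dead_poison, n_dead_other  (year labels the start of the
    interval in which the deaths occurred)
``histories.csv``
    id, sex, release_year, then one column per study year (``y1999``,
    ...) holding event codes 1-16, with 0 before release.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .multistate import EncounterHistory

__all__ = ["DatasetBundle", "read_bundle", "write_bundle"]


@dataclass
class DatasetBundle:
    """The four aligned data streams; unit of input to inference."""

    years: np.ndarray
    counts: pd.DataFrame
    productivity: pd.DataFrame
    recoveries: pd.DataFrame | None
    histories: list[EncounterHistory]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.validate()

    @property
    def n_years(self) -> int:
        return len(self.years)

    def validate(self) -> None:
        yrs = set(self.years.tolist())
        if self.counts is not None:
            _check_columns("counts", self.counts, ["year", "breeding_pairs"])
            _check_nonneg("counts", self.counts, "breeding_pairs")
            if not set(self.counts["year"]).issubset(yrs):
                raise ValueError("counts contain years outside the study index")
        if self.productivity is not None:
            _check_columns(
                "productivity", self.productivity,
                ["year", "n_broods", "n_fledglings"],
            )
            _check_nonneg("productivity", self.productivity, "n_broods")
            _check_nonneg("productivity", self.productivity, "n_fledglings")
            bad = self.productivity.query("n_broods == 0 and n_fledglings > 0")
            if len(bad):
                raise ValueError(
                    f"productivity rows with fledglings but no broods: "
                    f"years {bad['year'].tolist()}"
                )
        if self.recoveries is not None:
            _check_columns(
                "recoveries", self.recoveries,
                ["year", "n_dead_poison", "n_dead_other"],
            )
            _check_nonneg("recoveries", self.recoveries, "n_dead_poison")
            _check_nonneg("recoveries", self.recoveries, "n_dead_other")
        for h in self.histories:
            if len(h.events) != self.n_years:
                raise ValueError(
                    f"history {h.individual!r} has {len(h.events)} events, "
                    f"expected {self.n_years}"
                )

    # -- array views used by the inference code -------------------------
    def count_vector(self) -> np.ndarray:
        s = self.counts.set_index("year")["breeding_pairs"]
        return s.reindex(self.years).to_numpy(dtype=float)

    def productivity_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        df = self.productivity.set_index("year").reindex(self.years).fillna(0)
        return (
            df["n_broods"].to_numpy(dtype=int),
            df["n_fledglings"].to_numpy(dtype=int),
        )

    def recovery_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(RP, RO) over the n_years-1 between-occasion intervals."""
        intervals = self.years[:-1]
        df = self.recoveries.set_index("year").reindex(intervals).fillna(0)
        return (
            df["n_dead_poison"].to_numpy(dtype=int),
            df["n_dead_other"].to_numpy(dtype=int),
        )


def _check_columns(name: str, df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")


def _check_nonneg(name: str, df: pd.DataFrame, col: str) -> None:
    bad = df.index[df[col] < 0]
    if len(bad):
        raise ValueError(f"{name}: negative {col} in rows {bad.tolist()}")


def _histories_frame(bundle: DatasetBundle) -> pd.DataFrame:
    cols = {f"y{y}": [] for y in bundle.years}
    rows = []
    for h in bundle.histories:
        rows.append(
            {"id": h.individual, "sex": h.sex,
             "release_year": int(bundle.years[h.release_index])}
            | {f"y{y}": e for y, e in zip(bundle.years, h.events)}
        )
    return pd.DataFrame(rows, columns=["id", "sex", "release_year", *cols])


def _parse_histories(df: pd.DataFrame, years: np.ndarray) -> list[EncounterHistory]:
    ycols = [f"y{y}" for y in years]
    missing = [c for c in ycols if c not in df.columns]
    if missing:
        raise ValueError(f"histories: missing year columns {missing}")
    out = []
    year_index = {int(y): i for i, y in enumerate(years)}
    for i, row in df.iterrows():
        ry = int(row["release_year"])
        if ry not in year_index:
            raise ValueError(f"histories row {i}: release year {ry} outside study")
        events = tuple(int(row[c]) for c in ycols)
        if any(not 0 <= e <= 16 for e in events):
            raise ValueError(f"histories row {i} (id {row['id']!r}): "
                             "event code outside 0..16")
        try:
            out.append(
                EncounterHistory(str(row["id"]), str(row["sex"]),
                                 year_index[ry], events)
            )
        except ValueError as err:
            raise ValueError(f"histories row {i}: {err}") from err
    return out


def read_bundle(
    counts: str | Path,
    productivity: str | Path,
    histories: str | Path,
    recoveries: str | Path | None = None,
) -> DatasetBundle:
    """Load and validate the data streams; ``recoveries`` may be omitted
    when fitting a variant that does not use them."""
    cdf = pd.read_csv(counts)
    _check_columns("counts", cdf, ["year", "breeding_pairs"])
    years = np.sort(cdf["year"].to_numpy(dtype=int))
    pdf = pd.read_csv(productivity)
    rdf = pd.read_csv(recoveries) if recoveries is not None else None
    hdf = pd.read_csv(histories)
    return DatasetBundle(
        years=years,
        counts=cdf,
        productivity=pdf,
        recoveries=rdf,
        histories=_parse_histories(hdf, years),
        meta={"source": str(counts)},
    )


def write_bundle(bundle: DatasetBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the four CSVs; returns the paths keyed by stream name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.csv",
        "productivity": outdir / "productivity.csv",
        "histories": outdir / "histories.csv",
    }
    bundle.counts.to_csv(paths["counts"], index=False)
    bundle.productivity.to_csv(paths["productivity"], index=False)
    _histories_frame(bundle).to_csv(paths["histories"], index=False)
    if bundle.recoveries is not None:
        paths["recoveries"] = outdir / "recoveries.csv"
        bundle.recoveries.to_csv(paths["recoveries"], index=False)
    return paths
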