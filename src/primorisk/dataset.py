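"""Residue measurements of a monitoring campaign and their descriptive stats.

A campaign is a set of quantified detections — one row per (sample,
substance) — plus the total number of samples collected, which exceeds the
number of samples appearing in the rows because residue-free samples leave
no trace in the table. The limit of quantification (LOQ) bounds every kept
concentration from below; values under it are non-detects and are censored
out, not replaced.

The per-substance mean is computed over detected samples only (the
"Average Pesticide Residue" convention of single-campaign assessments,
standing in for the supervised-trials median residue). This inflates the
mean relative to a whole-campaign average that would count non-detects as
zero; chronic exposure computed from it is correspondingly conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .reference import PesticideRef, normalize_name

DEFAULT_LOQ = 0.010  # mg/kg

_COLUMNS = ["sample_id", "pesticide", "concentration"]


@dataclass(frozen=True)
class ResidueMeasurement:
    """One quantified detection of one substance in one field sample."""

    sample_id: str
    pesticide: str
    concentration: float

    def __post_init__(self) -> None:
        if not (self.concentration > 0 and math.isfinite(self.concentration)):
            raise ValueError(
                f"{self.sample_id}/{self.pesticide}: concentration must be a "
                f"positive number, got {self.concentration!r}"
            )


@dataclass(frozen=True)
class PesticideSummary:
    """Detection count and concentration summary for one substance."""

    pesticide: str
    n_detect: int
    mean: float
    min: float
    max: float
    total: float


@dataclass(frozen=True)
class ResidueDataset:
    """All detections of a campaign plus campaign-level metadata.

    ``n_samples_total`` counts every sample collected, including residue-free
    ones that have no measurement rows.
    """

    measurements: tuple[ResidueMeasurement, ...]
    n_samples_total: int
    loq: float = DEFAULT_LOQ
    n_censored: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.loq <= 0:
            raise ValueError(f"loq must be positive, got {self.loq}")
        seen: set[tuple[str, str]] = set()
        for m in self.measurements:
            key = (m.sample_id, m.pesticide)
            if key in seen:
                raise ValueError(f"duplicate measurement for sample/pesticide {key}")
            seen.add(key)
        n_with = len({m.sample_id for m in self.measurements})
        if self.n_samples_total < n_with:
            raise ValueError(
                f"n_samples_total={self.n_samples_total} is below the "
                f"{n_with} distinct samples carrying measurements"
            )

    @property
    def pesticides(self) -> tuple[str, ...]:
        return tuple(sorted({m.pesticide for m in self.measurements}))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(sorted({m.sample_id for m in self.measurements}))

    def sample(self, sample_id: str) -> tuple[ResidueMeasurement, ...]:
        return tuple(m for m in self.measurements if m.sample_id == sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.sample_id, m.pesticide, m.concentration) for m in self.measurements],
            columns=_COLUMNS,
        )


def read_residues(
    path: str | Path, n_samples_total: int | None = None, loq: float = DEFAULT_LOQ
) -> ResidueDataset:
    """Read a residue CSV (``sample_id,pesticide,concentration_mg_kg``).

    Names are canonicalized; ``#`` lines are comments. Malformed or
    non-positive concentrations and duplicate (sample, pesticide) pairs are
    hard errors naming the offending line. When ``n_samples_total`` is not
    given, the distinct sample count in the file is used (i.e. the file is
    assumed to cover the whole campaign with no residue-free samples).
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#", dtype=str)
    expected = {"sample_id", "pesticide", "concentration_mg_kg"}
    if not expected.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}, got {list(frame.columns)}")
    measurements = []
    for line, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            conc = float(row.concentration_mg_kg)
        except (TypeError, ValueError) as err:
            raise ValueError(
                f"{path}, data row {line}: non-numeric concentration "
                f"{row.concentration_mg_kg!r}"
            ) from err
        if conc <= 0:
            raise ValueError(f"{path}, data row {line}: non-positive concentration {conc}")
        measurements.append(
            ResidueMeasurement(str(row.sample_id).strip(), normalize_name(row.pesticide), conc)
        )
    if n_samples_total is None:
        n_samples_total = len({m.sample_id for m in measurements})
    return ResidueDataset(tuple(measurements), n_samples_total=n_samples_total, loq=loq)


def write_residues(dataset: ResidueDataset, path: str | Path) -> None:
    frame = dataset.to_frame().rename(columns={"concentration": "concentration_mg_kg"})
    frame.to_csv(path, index=False)


def censor_loq(dataset: ResidueDataset, loq: float | None = None) -> ResidueDataset:
    """Drop measurements strictly below the LOQ.

    The boundary value is kept (a concentration equal to the LOQ is a valid
    quantification). ``n_samples_total`` is unchanged — a censored sample is
    still a collected sample — and the number of removed rows is recorded on
    ``n_censored``.
    """
    if loq is None:
        loq = dataset.loq
    if loq <= 0:
        raise ValueError(f"loq must be positive, got {loq}")
    kept = tuple(m for m in dataset.measurements if m.concentration >= loq)
    return ResidueDataset(
        kept,
        n_samples_total=dataset.n_samples_total,
        loq=loq,
        n_censored=dataset.n_censored + len(dataset.measurements) - len(kept),
    )


def summarize(dataset: ResidueDataset, pesticide: str) -> PesticideSummary:
    """Mean/min/max/total over the samples where ``pesticide`` was detected.

    Raises ``KeyError`` if the substance has no detections — callers must
    not silently conflate "not monitored" with "zero residue".
    """
    pesticide = normalize_name(pesticide)
    values = [m.concentration for m in dataset.measurements if m.pesticide == pesticide]
    if not values:
        raise KeyError(f"no detections for pesticide {pesticide!r}")
    total = math.fsum(values)
    return PesticideSummary(
        pesticide=pesticide,
        n_detect=len(values),
        mean=total / len(values),
        min=min(values),
        max=max(values),
        total=total,
    )


def summarize_all(dataset: ResidueDataset) -> dict[str, PesticideSummary]:
    """Per-substance summaries for every detected substance, sorted by name."""
    return {p: summarize(dataset, p) for p in dataset.pesticides}


def class_composition(
    totals: ResidueDataset | dict[str, float],
    refs: dict[str, PesticideRef],
) -> tuple[dict[str, float], dict[str, float]]:
    """Share of the grand total concentration per class and per substance.

    ``totals`` is either a dataset (per-substance totals are computed from
    its rows) or a precomputed ``{pesticide: total}`` mapping, e.g. from a
    published campaign summary. Returns ``(class_shares, pesticide_shares)``
    in percent; each set of shares sums to 100 before rounding. Every
    substance must carry a class in ``refs``.
    """
    if isinstance(totals, ResidueDataset):
        totals = {p: s.total for p, s in summarize_all(totals).items()}
    else:
        totals = {normalize_name(p): t for p, t in totals.items()}
    missing = sorted(set(totals) - set(refs))
    if missing:
        raise KeyError(f"pesticides without a class reference: {missing}")
    grand = math.fsum(totals.values())
    if grand <= 0:
        raise ValueError("grand total concentration is zero; no shares defined")
    pesticide_shares = {p: t / grand * 100.0 for p, t in totals.items()}
    class_shares: dict[str, float] = {}
    for p, share in pesticide_shares.items():
        pclass = refs[p].pclass
        class_shares[pclass] = class_shares.get(pclass, 0.0) + share
    return class_shares, pesticide_shares


def residue_count_distribution(dataset: ResidueDataset) -> dict[int, float]:
    """Percent of samples by number of residues detected, including zero.

    The zero bucket covers the collected samples with no measurement rows.
    Percentages sum to 100 before rounding.
    """
    counts: dict[str, int] = {}
    for m in dataset.measurements:
        counts[m.sample_id] = counts.get(m.sample_id, 0) + 1
    dist: dict[int, int] = {}
    for n in counts.values():
        dist[n] = dist.get(n, 0) + 1
    n_zero = dataset.n_samples_total - len(counts)
    if n_zero > 0:
        dist[0] = n_zero
    return {
        k: dist[k] / dataset.n_samples_total * 100.0 for k in sorted(dist)
    }
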