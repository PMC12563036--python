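"""MRL compliance scoring.

Each measurement is expressed as a percentage of the substance's legal
Maximum Residue Limit; a sample is non-compliant as soon as any one of its
residues strictly exceeds 100% of the MRL. The exceedance decision uses
the unrounded ratio: the MRL is a legal threshold, not a display value, so
a measurement at 100.4% flags even though the reported integer is 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dataset import ResidueDataset
from .reference import PesticideRef


@dataclass(frozen=True)
class ComplianceRecord:
    """One measurement scored against its MRL (percent at full precision)."""

    sample_id: str
    pesticide: str
    concentration: float
    mrl: float
    percent_mrl: float
    exceeds: bool


def percent_mrl(concentration: float, mrl: float) -> float:
    """``concentration / mrl * 100`` at full precision.

    Report layers round half-up to an integer; this function never rounds.
    """
    if mrl is None or not mrl > 0:
        raise ValueError(f"MRL must be a positive number, got {mrl!r}")
    if concentration < 0:
        raise ValueError(f"concentration must be non-negative, got {concentration}")
    return concentration / mrl * 100.0


def assess_compliance(
    dataset: ResidueDataset, refs: dict[str, PesticideRef]
) -> tuple[list[ComplianceRecord], list[str]]:
    """Score every measurement; return records plus non-compliant sample ids.

    Every substance in the dataset must have an MRL in ``refs`` (all EU
    commodity/substance pairs carry one); a missing reference is a hard
    error, not a silent pass.
    """
    missing = sorted(set(dataset.pesticides) - set(refs))
    if missing:
        raise KeyError(f"pesticides without an MRL reference: {missing}")
    records = []
    flagged: set[str] = set()
    for m in dataset.measurements:
        pct = percent_mrl(m.concentration, refs[m.pesticide].mrl)
        exceeds = pct > 100.0
        if exceeds:
            flagged.add(m.sample_id)
        records.append(
            ComplianceRecord(
                sample_id=m.sample_id,
                pesticide=m.pesticide,
                concentration=m.concentration,
                mrl=refs[m.pesticide].mrl,
                percent_mrl=pct,
                exceeds=exceeds,
            )
        )
    return records, sorted(flagged)
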