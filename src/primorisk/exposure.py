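"""Acute (IESTI/%ARfD) and chronic (NEDI/%ADI) dietary exposure.

Acute exposure follows the FAO/WHO IESTI scheme as implemented in EFSA's
PRIMo model. For a whole-unit commodity lighter than 25 g (Case 1, e.g.
strawberries) the short-term intake is

    IESTI = LP_kg x HR x PF x CF / BW        [mg per kg body weight]

with LP the subgroup's large portion (converted here from g/day), HR the
highest residue observed across the campaign, PF/CF processing and
conversion factors, and BW the subgroup body weight. Units above 25 g use
the unit-based variants (Cases 2a/2b) with a variability factor ``nu``
accounting for unit-to-unit residue variability:

    Case 2a: (U_kg x HR x nu + (LP_kg - U_kg) x HR) x PF x CF / BW
    Case 2b:  LP_kg x HR x nu x PF x CF / BW

Chronic exposure uses the campaign's average residue (APR, mean over
detected samples) and the subgroup's habitual consumption expressed per kg
body weight, so body weight cancels out of the formula:

    NEDI = APR x mean_consumption / 1000     [mg per kg bw per day]

Each estimate is judged against its toxicological reference value: the
exposure is acceptable when %ARfD (resp. %ADI) is below 100. Substances
with no established ARfD/ADI are reported as not assessable — never as
zero risk.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dataset import ResidueDataset, summarize_all
from .reference import ConsumptionProfile, PesticideRef

#: unit weight (g) above which the IESTI unit-based cases apply
UNIT_WEIGHT_CASE_THRESHOLD = 25.0


@dataclass(frozen=True)
class AcuteResult:
    """Acute exposure for one substance with an established ARfD."""

    pesticide: str
    hr: float  # highest residue across the campaign, mg/kg
    iesti: float  # mg/kg bw
    percent_arfd: float
    case_used: str  # "1", "2a" or "2b"


@dataclass(frozen=True)
class ChronicResult:
    """Chronic exposure for one substance with an established ADI."""

    pesticide: str
    apr: float  # mean residue over detected samples, mg/kg
    nedi: float  # mg/kg bw/day
    percent_adi: float


def iesti_case(profile: ConsumptionProfile) -> str:
    """IESTI case implied by the commodity unit weight.

    Below (or at) 25 g the whole-unit Case 1 applies; heavier units use
    Case 2a when a large portion spans several units, Case 2b when one unit
    exceeds the large portion.
    """
    if profile.unit_weight <= UNIT_WEIGHT_CASE_THRESHOLD:
        return "1"
    return "2a" if profile.unit_weight < profile.large_portion else "2b"


def iesti(hr: float, profile: ConsumptionProfile) -> float:
    """Short-term intake (mg/kg bw) for highest residue ``hr`` (mg/kg)."""
    if hr < 0:
        raise ValueError(f"highest residue must be non-negative, got {hr}")
    lp_kg = profile.large_portion / 1000.0
    u_kg = profile.unit_weight / 1000.0
    nu = profile.variability_factor
    factors = profile.processing_factor * profile.conversion_factor / profile.body_weight
    case = iesti_case(profile)
    if case == "1":
        return lp_kg * hr * factors
    if case == "2a":
        return (u_kg * hr * nu + (lp_kg - u_kg) * hr) * factors
    return lp_kg * hr * nu * factors


def percent_arfd(iesti_value: float, arfd: float | None) -> float:
    """Acute exposure as percent of the Acute Reference Dose."""
    if arfd is None:
        raise ValueError("ARfD not established; acute risk is not assessable")
    if not arfd > 0:
        raise ValueError(f"ARfD must be positive, got {arfd}")
    return iesti_value / arfd * 100.0


def nedi(apr: float, mean_consumption: float) -> float:
    """Long-term daily intake (mg/kg bw/day).

    ``mean_consumption`` is already per kg body weight (g/kg bw/day), so
    body weight does not appear; /1000 converts grams to kilograms.
    """
    if apr < 0:
        raise ValueError(f"average residue must be non-negative, got {apr}")
    if not mean_consumption > 0:
        raise ValueError(f"mean consumption must be positive, got {mean_consumption}")
    return apr * mean_consumption / 1000.0


def percent_adi(nedi_value: float, adi: float | None) -> float:
    """Chronic exposure as percent of the Acceptable Daily Intake."""
    if adi is None:
        raise ValueError("ADI not established; chronic risk is not assessable")
    if not adi > 0:
        raise ValueError(f"ADI must be positive, got {adi}")
    return nedi_value / adi * 100.0


def _check_refs(dataset: ResidueDataset, refs: dict[str, PesticideRef]) -> None:
    missing = sorted(set(dataset.pesticides) - set(refs))
    if missing:
        raise KeyError(f"pesticides without a toxicological reference: {missing}")


def assess_acute(
    dataset: ResidueDataset,
    refs: dict[str, PesticideRef],
    profile: ConsumptionProfile,
) -> tuple[list[AcuteResult], list[str]]:
    """Acute assessment for every detected substance with an ARfD.

    HR is the maximum concentration across the whole campaign (worst-case
    single-portion scenario). Returns ``(results, not_assessable)`` where
    the second list names substances lacking an established ARfD.
    """
    if not dataset.measurements:
        raise ValueError("dataset has no measurements")
    _check_refs(dataset, refs)
    case = iesti_case(profile)
    results = []
    not_assessable = []
    for pesticide, summary in summarize_all(dataset).items():
        arfd = refs[pesticide].arfd
        if arfd is None:
            not_assessable.append(pesticide)
            continue
        intake = iesti(summary.max, profile)
        results.append(
            AcuteResult(
                pesticide=pesticide,
                hr=summary.max,
                iesti=intake,
                percent_arfd=percent_arfd(intake, arfd),
                case_used=case,
            )
        )
    return results, not_assessable


def assess_chronic(
    dataset: ResidueDataset,
    refs: dict[str, PesticideRef],
    profile: ConsumptionProfile,
) -> tuple[list[ChronicResult], list[str]]:
    """Chronic assessment for every detected substance with an ADI.

    APR is the mean over detected samples (see :mod:`primorisk.dataset` for
    the convention and the conservatism it implies).
    """
    if not dataset.measurements:
        raise ValueError("dataset has no measurements")
    _check_refs(dataset, refs)
    results = []
    not_assessable = []
    for pesticide, summary in summarize_all(dataset).items():
        adi = refs[pesticide].adi
        if adi is None:
            not_assessable.append(pesticide)
            continue
        intake = nedi(summary.mean, profile.mean_consumption)
        results.append(
            ChronicResult(
                pesticide=pesticide,
                apr=summary.mean,
                nedi=intake,
                percent_adi=percent_adi(intake, adi),
            )
        )
    return results, not_assessable


def hazard_index(
    sample_id: str,
    dataset: ResidueDataset,
    refs: dict[str, PesticideRef],
    profile: ConsumptionProfile,
) -> tuple[float, list[str]]:
    """First-tier cumulative screen for one sample: sum of per-residue %ARfD.

    Each residue's own concentration in the sample acts as its HR (the whole
    sample is eaten in one sitting), assuming dose additivity across
    substances. Residues without an established ARfD cannot enter the sum
    and are returned as the exclusion list — a hazard index with exclusions
    is a lower bound, not a clean bill.
    """
    measurements = dataset.sample(sample_id)
    if not measurements:
        raise KeyError(f"sample {sample_id!r} has no measurements in this dataset")
    total = 0.0
    excluded = []
    for m in measurements:
        arfd = refs[m.pesticide].arfd
        if arfd is None:
            excluded.append(m.pesticide)
            continue
        total += percent_arfd(iesti(m.concentration, profile), arfd)
    return total, sorted(excluded)
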