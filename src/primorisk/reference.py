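"""Regulatory reference values, consumption profiles and name canonicalization.

The toxicological reference table holds, per active substance, the legal
Maximum Residue Limit (MRL, mg kg-1), the Acute Reference Dose (ARfD,
mg kg-1 bw) and the Acceptable Daily Intake (ADI, mg kg-1 bw/day). ARfD and
ADI are *not established* for every substance; that state is encoded as
``None`` — never as zero or infinity — and downstream assessments must skip
such substances explicitly.

Monitoring reports frequently mix language variants of substance names
(e.g. Italian "Bupirimato" vs "Bupirimate"); :func:`normalize_name` folds
all spellings occurring in the bundled tables onto one canonical name.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

VALID_CLASSES = frozenset({"fungicide", "acaricide", "insecticide"})

#: raw (lower-cased, whitespace-collapsed) spelling -> canonical name.
#: Total over every variant appearing in the bundled fixture tables.
SYNONYMS: dict[str, str] = {
    "hexithiazox": "hexythiazox",
    "tebufenaprid": "tebufenpyrad",
    "bifenazato": "bifenazate",
    "bupirimato": "bupirimate",
    "difenconazolo": "difenoconazole",
    "difenoconazolo": "difenoconazole",
    "penconazolo": "penconazole",
    "etirimol": "ethirimol",
    "pirimentanil": "pyrimethanil",
    "tetraconazolo": "tetraconazole",
    "captano": "captan",
    "clorantraniliprolo": "chlorantraniliprole",
    "lambda cialotrina": "lambda-cyhalothrin",
    "lambda-cialotrina": "lambda-cyhalothrin",
    "spirotetrammato": "spirotetramat",
    "emamectina": "emamectin",
    "emamectin benzoate": "emamectin",
    "fluopiram": "fluopyram",
    "cyflumetofene": "cyflumetofen",
}


def normalize_name(raw: str) -> str:
    """Return the canonical active-substance name for ``raw``.

    Lookup is case-insensitive and whitespace-insensitive and idempotent on
    canonical names. Unknown names are returned lower-cased with a logged
    warning rather than raising, so a novel substance does not abort a run.
    """
    key = re.sub(r"\s+", " ", raw.strip().lower())
    if key in SYNONYMS:
        return SYNONYMS[key]
    if key not in _KNOWN_CANONICAL:
        logger.warning("unrecognized pesticide name %r; using %r as-is", raw, key)
    return key


# Canonical names recognized without a warning: the synonym targets, the 31
# substances of the bundled tables, and anything later loaded from a user
# reference table.
_KNOWN_CANONICAL: set[str] = set(SYNONYMS.values()) | {
    "hexythiazox", "cyflumetofen", "tebufenpyrad", "bifenazate", "fenpyroximate",
    "bupirimate", "fluxapyroxad", "difenoconazole", "cyflufenamid", "penconazole",
    "cyprodinil", "fludioxonil", "ethirimol", "pyrimethanil", "fluopyram",
    "trifloxystrobin", "tetraconazole", "boscalid", "fenhexamid", "captan",
    "penthiopyrad", "azoxystrobin", "spinosad", "chlorantraniliprole",
    "flupyradifurone", "lambda-cyhalothrin", "spirotetramat", "spinetoram",
    "pirimicarb", "emamectin", "acetamiprid",
}


@dataclass(frozen=True)
class PesticideRef:
    """Regulatory constants for one active substance.

    ``arfd`` / ``adi`` are ``None`` when the authority has not established
    the value ("-" / "Not applicable" in source tables).
    """

    name: str
    pclass: str
    mrl: float
    arfd: float | None = None
    adi: float | None = None

    def __post_init__(self) -> None:
        if self.pclass not in VALID_CLASSES:
            raise ValueError(
                f"{self.name}: class must be one of {sorted(VALID_CLASSES)}, "
                f"got {self.pclass!r}"
            )
        if not (self.mrl > 0 and math.isfinite(self.mrl)):
            raise ValueError(f"{self.name}: MRL must be positive, got {self.mrl}")
        for field, value in (("ARfD", self.arfd), ("ADI", self.adi)):
            if value is not None and not (value > 0 and math.isfinite(value)):
                raise ValueError(
                    f"{self.name}: {field} must be positive when present, got {value}"
                )


@dataclass(frozen=True)
class ConsumptionProfile:
    """Population parameters driving both exposure models.

    body_weight      kg, subgroup reference body weight (BW)
    large_portion    g/day, high-end single-day consumption (LP)
    mean_consumption g/kg bw/day, habitual intake per kg body weight
    unit_weight      g, weight of one commodity unit; decides the IESTI case
    processing_factor, conversion_factor  dimensionless, default 1
    variability_factor dimensionless, default 1; used only by IESTI
                       Cases 2a/2b (within-lot unit-to-unit variability)
    """

    label: str
    body_weight: float
    large_portion: float
    mean_consumption: float
    unit_weight: float
    processing_factor: float = 1.0
    conversion_factor: float = 1.0
    variability_factor: float = 1.0

    def __post_init__(self) -> None:
        for field in (
            "body_weight",
            "large_portion",
            "mean_consumption",
            "unit_weight",
            "processing_factor",
            "conversion_factor",
            "variability_factor",
        ):
            value = getattr(self, field)
            if not (isinstance(value, (int, float)) and value > 0 and math.isfinite(value)):
                raise ValueError(f"profile {self.label!r}: {field} must be positive, got {value!r}")


_ABSENT = {"", "-", "na", "n/a", "not applicable", "none"}


def _parse_optional(text: str, field: str, row: str) -> float | None:
    cell = text.strip()
    if cell.lower() in _ABSENT:
        return None
    try:
        value = float(cell)
    except ValueError as err:
        raise ValueError(f"row {row!r}: cannot parse {field}={cell!r}") from err
    return value


def load_reference_table(path: str | Path) -> dict[str, PesticideRef]:
    """Load a reference CSV into ``{canonical name: PesticideRef}``.

    Expected columns: ``pesticide,class,mrl_mg_kg,arfd_mg_kg_bw,
    adi_mg_kg_bw_day``; ``#`` lines are comments; "-" or "Not applicable"
    mark an unestablished ARfD/ADI. Duplicate canonical names and
    non-positive MRLs are hard errors.
    """
    path = Path(path)
    refs: dict[str, PesticideRef] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        rows = csv.DictReader(filter(lambda line: not line.lstrip().startswith("#"), handle))
        required = {"pesticide", "class", "mrl_mg_kg", "arfd_mg_kg_bw", "adi_mg_kg_bw_day"}
        if rows.fieldnames is None or not required.issubset(rows.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}, got {rows.fieldnames}")
        for record in rows:
            name = normalize_name(record["pesticide"])
            if name in refs:
                raise ValueError(f"{path}: duplicate pesticide {name!r}")
            mrl = _parse_optional(record["mrl_mg_kg"], "mrl", name)
            if mrl is None or mrl <= 0:
                raise ValueError(f"{path}: row {name!r} has non-positive or missing MRL")
            refs[name] = PesticideRef(
                name=name,
                pclass=record["class"].strip().lower(),
                mrl=mrl,
                arfd=_parse_optional(record["arfd_mg_kg_bw"], "arfd", name),
                adi=_parse_optional(record["adi_mg_kg_bw_day"], "adi", name),
            )
    _KNOWN_CANONICAL.update(refs)
    return refs


def write_reference_table(refs: dict[str, PesticideRef], path: str | Path) -> None:
    """Write ``refs`` back to CSV in the canonical column order."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["pesticide", "class", "mrl_mg_kg", "arfd_mg_kg_bw", "adi_mg_kg_bw_day"])
        for ref in refs.values():
            writer.writerow(
                [
                    ref.name,
                    ref.pclass,
                    repr(ref.mrl),
                    "-" if ref.arfd is None else repr(ref.arfd),
                    "-" if ref.adi is None else repr(ref.adi),
                ]
            )


def _profile_from_mapping(label: str, entry: dict) -> ConsumptionProfile:
    def grab(key: str, default: float | None = None) -> float:
        if key in entry:
            return float(entry[key])
        if default is None:
            raise ValueError(f"profile {label!r}: missing required field {key!r}")
        return default

    return ConsumptionProfile(
        label=str(entry.get("label", label)),
        body_weight=grab("body_weight_kg"),
        large_portion=grab("large_portion_g_day"),
        mean_consumption=grab("mean_consumption_g_kgbw_day"),
        unit_weight=grab("unit_weight_g"),
        processing_factor=grab("processing_factor", 1.0),
        conversion_factor=grab("conversion_factor", 1.0),
        variability_factor=grab("variability_factor", 1.0),
    )


def load_profiles(path: str | Path | None = None) -> dict[str, ConsumptionProfile]:
    """Load all consumption profiles from a YAML file (bundled by default)."""
    if path is None:
        path = bundled_path("profiles.yaml")
    with Path(path).open(encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict) or "profiles" not in doc:
        raise ValueError(f"{path}: expected a top-level 'profiles' mapping")
    return {key: _profile_from_mapping(key, entry) for key, entry in doc["profiles"].items()}


def load_consumption_profile(
    name: str = "nl_toddler", path: str | Path | None = None
) -> ConsumptionProfile:
    """Return one named profile; default is the NL-toddler profile."""
    profiles = load_profiles(path)
    if name not in profiles:
        raise KeyError(f"unknown consumption profile {name!r}; have {sorted(profiles)}")
    return profiles[name]


def bundled_path(filename: str) -> Path:
    """Filesystem path of a data file shipped with the package."""
    return Path(resources.files("primorisk.data") / filename)
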