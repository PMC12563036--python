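"""Seeded synthetic monitoring campaigns.

Real multiresidue campaigns are rarely deposited sample by sample; what
survives is a per-substance summary (detection frequency, mean, max). This
module turns such a summary into a generative model so every pipeline
stage can be exercised on data with the right statistical structure:

* per-substance Bernoulli detection at the campaign's observed frequency;
* right-skewed concentrations from a lognormal whose parameters are
  matched to the published mean and maximum (the maximum is treated as the
  99th percentile — only summary statistics are available, so a formal fit
  is not possible);
* censoring at the limit of quantification by redraw (up to 100 attempts,
  then clamping to the LOQ), which preserves the detection frequency
  exactly instead of silently thinning detections;
* fixed co-occurrence pairs (mixed commercial formulations): wherever the
  trigger substance is detected the companion is detected too, with the
  companion's remaining probability adjusted so its marginal detection
  frequency stays at the configured value;
* optionally, inflation of one substance's upper tail above its MRL to
  emulate sporadic non-compliance.

Every substance draws from its own random stream derived from the global
seed and a stable hash of its name, so adding or removing a substance does
not perturb the others' draws.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DEFAULT_LOQ, ResidueDataset, ResidueMeasurement
from .reference import bundled_path, load_reference_table, normalize_name

_Z99 = 2.3263478740408408  # standard normal 99th percentile
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class PesticideModel:
    """Generative description of one substance's occurrence."""

    detection_prob: float
    log_mean: float  # mu of ln-concentration
    log_sd: float  # sigma of ln-concentration, > 0
    pclass: str = "fungicide"

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError(f"detection_prob must be in [0, 1], got {self.detection_prob}")
        if not self.log_sd > 0:
            raise ValueError(f"log_sd must be positive, got {self.log_sd}")

    @property
    def mean_concentration(self) -> float:
        """Mean of the (untruncated) lognormal concentration law, mg/kg."""
        return math.exp(self.log_mean + self.log_sd**2 / 2)


@dataclass(frozen=True)
class MRLExceedance:
    """Upper-tail inflation: with probability ``rate`` a detection of
    ``pesticide`` is replaced by a draw uniformly in (1.05, 1.5) x MRL."""

    pesticide: str
    mrl: float
    rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")
        if not self.mrl > 0:
            raise ValueError(f"mrl must be positive, got {self.mrl}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Seeded description of a whole monitoring campaign."""

    seed: int
    n_samples: int
    pesticides: dict[str, PesticideModel]
    loq: float = DEFAULT_LOQ
    co_occurrence_pairs: tuple[tuple[str, str], ...] = ()
    mrl_exceedance: MRLExceedance | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if not self.loq > 0:
            raise ValueError(f"loq must be positive, got {self.loq}")
        for trigger, companion in self.co_occurrence_pairs:
            for name in (trigger, companion):
                if name not in self.pesticides:
                    raise ValueError(f"co-occurrence names unknown pesticide {name!r}")
            if self.pesticides[companion].detection_prob < self.pesticides[trigger].detection_prob:
                raise ValueError(
                    f"companion {companion!r} must be at least as frequent as "
                    f"trigger {trigger!r} to preserve its marginal frequency"
                )
        triggers = [t for t, _ in self.co_occurrence_pairs]
        companions = [c for _, c in self.co_occurrence_pairs]
        if set(triggers) & set(companions) or len(set(companions)) != len(companions):
            raise ValueError("co-occurrence pairs must form disjoint trigger->companion links")


def match_lognormal(mean: float, maximum: float, p: float = 0.99) -> tuple[float, float]:
    """Lognormal (mu, sigma) with the given mean and ``maximum`` as the
    p-quantile. Falls back to a narrow law (sigma 0.2) when mean == max
    (single-detection substances carry no spread information)."""
    if not (mean > 0 and maximum >= mean):
        raise ValueError(f"need 0 < mean <= max, got mean={mean}, max={maximum}")
    z = _z_for(p)
    disc = z**2 - 2 * math.log(maximum / mean)
    sigma = z - math.sqrt(disc) if disc > 0 else z
    if sigma <= 0:
        sigma = 0.2
    mu = math.log(mean) - sigma**2 / 2
    return mu, sigma


def _z_for(p: float) -> float:
    if p == 0.99:
        return _Z99
    # Acklam-style inverse normal is overkill here; binary search suffices.
    lo, hi = 0.0, 10.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if 0.5 * math.erfc(-mid / math.sqrt(2)) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _stable_hash(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big") % (2**31)


def default_study_config(
    seed: int = 0,
    n_samples: int = 83,
    summary_path=None,
) -> SyntheticConfig:
    """Config emulating the bundled 83-sample strawberry campaign.

    Detection probabilities are the campaign's detection counts over its 83
    collected samples (independent of the ``n_samples`` generated); lognormal
    parameters are matched to each substance's published mean and maximum.
    The two fixed formulation pairs of the campaign (trifloxystrobin with
    fluopyram, difenoconazole with fluxapyroxad) are enforced as
    co-occurrences.
    """
    if summary_path is None:
        summary_path = bundled_path("campaign_summary.csv")
    refs = load_reference_table(bundled_path("references.csv"))
    frame = pd.read_csv(summary_path, comment="#")
    campaign_size = 83
    models: dict[str, PesticideModel] = {}
    for row in frame.itertuples(index=False):
        name = normalize_name(row.pesticide)
        mu, sigma = match_lognormal(float(row.mean_mg_kg), float(row.max_mg_kg))
        models[name] = PesticideModel(
            detection_prob=float(row.n_detect) / campaign_size,
            log_mean=mu,
            log_sd=sigma,
            pclass=refs[name].pclass if name in refs else "fungicide",
        )
    return SyntheticConfig(
        seed=seed,
        n_samples=n_samples,
        pesticides=models,
        loq=DEFAULT_LOQ,
        co_occurrence_pairs=(
            ("trifloxystrobin", "fluopyram"),
            ("difenoconazole", "fluxapyroxad"),
        ),
    )


def _sample_ids(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return [f"{letters[i % 26]}{i // 26 + 1}" for i in range(n)]


def _draw_concentrations(
    rng: np.random.Generator, model: PesticideModel, n: int, loq: float
) -> np.ndarray:
    values = rng.lognormal(model.log_mean, model.log_sd, size=n)
    for _ in range(_MAX_REDRAWS):
        below = values < loq
        if not below.any():
            break
        values[below] = rng.lognormal(model.log_mean, model.log_sd, size=int(below.sum()))
    return np.maximum(values, loq)


def generate(config: SyntheticConfig) -> ResidueDataset:
    """Draw one campaign; fully deterministic given ``config.seed``."""
    companions = {c: t for t, c in config.co_occurrence_pairs}
    ids = _sample_ids(config.n_samples)
    masks: dict[str, np.ndarray] = {}
    uniforms: dict[str, np.ndarray] = {}
    rngs = {
        name: np.random.default_rng([config.seed, _stable_hash(name)])
        for name in config.pesticides
    }
    for name, model in config.pesticides.items():
        uniforms[name] = rngs[name].random(config.n_samples)
        masks[name] = uniforms[name] < model.detection_prob
    for companion, trigger in companions.items():
        p_c = config.pesticides[companion].detection_prob
        p_t = config.pesticides[trigger].detection_prob
        residual = 0.0 if p_t >= 1.0 else (p_c - p_t) / (1.0 - p_t)
        masks[companion] = masks[trigger] | (
            ~masks[trigger] & (uniforms[companion] < residual)
        )
    measurements: list[ResidueMeasurement] = []
    for name, model in config.pesticides.items():
        detected = np.flatnonzero(masks[name])
        if detected.size == 0:
            continue
        values = _draw_concentrations(rngs[name], model, detected.size, config.loq)
        exc = config.mrl_exceedance
        if exc is not None and normalize_name(exc.pesticide) == name and exc.rate > 0:
            hit = rngs[name].random(detected.size) < exc.rate
            values[hit] = exc.mrl * rngs[name].uniform(1.05, 1.5, size=int(hit.sum()))
        for idx, value in zip(detected, values):
            measurements.append(ResidueMeasurement(ids[idx], name, float(value)))
    measurements.sort(key=lambda m: (m.sample_id, m.pesticide))
    return ResidueDataset(
        tuple(measurements), n_samples_total=config.n_samples, loq=config.loq
    )
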