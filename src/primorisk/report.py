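"""Pipeline orchestration and deterministic CSV/text reporting.

Full float precision is carried through every stage; rounding happens here
and only here: concentrations and percentage shares at 2 decimals,
MRL percentages as integers, all half-up. Re-running on identical inputs
produces byte-identical files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._rounding import round_half_up
from .compliance import assess_compliance
from .dataset import (
    ResidueDataset,
    censor_loq,
    class_composition,
    read_residues,
    residue_count_distribution,
    summarize_all,
)
from .exposure import assess_acute, assess_chronic, hazard_index
from .reference import (
    ConsumptionProfile,
    PesticideRef,
    bundled_path,
    load_consumption_profile,
    load_reference_table,
)

logger = logging.getLogger(__name__)

NOT_APPLICABLE = "-"


@dataclass
class PipelineConfig:
    """What to run, on which inputs, writing where."""

    residue_path: Path
    reference_path: Path
    output_dir: Path
    profile: ConsumptionProfile
    loq: float = 0.010
    n_samples_total: int | None = None
    run_summary: bool = True
    run_compliance: bool = True
    run_acute: bool = True
    run_chronic: bool = True
    run_hazard_index: bool = True

    def __post_init__(self) -> None:
        if not any(
            (
                self.run_summary,
                self.run_compliance,
                self.run_acute,
                self.run_chronic,
                self.run_hazard_index,
            )
        ):
            raise ValueError("at least one pipeline stage must be enabled")


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, before and after rounding."""

    dataset: ResidueDataset
    files: dict[str, Path] = field(default_factory=dict)
    summary_lines: list[str] = field(default_factory=list)


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n")


def _fmt_pct(value: float | None, ndigits: int = 2) -> float | str:
    if value is None:
        return NOT_APPLICABLE
    return round_half_up(value, ndigits)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every enabled stage, writing one CSV per stage plus a text
    summary naming non-compliant samples and the most exposed substances."""
    t0 = time.perf_counter()
    refs = load_reference_table(config.reference_path)
    raw = read_residues(
        config.residue_path, n_samples_total=config.n_samples_total, loq=config.loq
    )
    dataset = censor_loq(raw, config.loq)
    logger.info(
        "loaded %d measurements (%d censored below LOQ %.3g) from %s",
        len(raw.measurements),
        dataset.n_censored,
        config.loq,
        config.residue_path,
    )
    config.output_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(dataset=dataset)
    lines = bundle.summary_lines
    lines.append(f"samples: {dataset.n_samples_total}")
    lines.append(f"measurements: {len(dataset.measurements)} (censored: {dataset.n_censored})")
    lines.append(f"pesticides detected: {len(dataset.pesticides)}")

    if config.run_summary:
        _stage_summary(dataset, refs, config.output_dir, bundle)
    if config.run_compliance:
        _stage_compliance(dataset, refs, config.output_dir, bundle)
    if config.run_acute and dataset.measurements:
        _stage_acute(dataset, refs, config.profile, config.output_dir, bundle)
    if config.run_chronic and dataset.measurements:
        _stage_chronic(dataset, refs, config.profile, config.output_dir, bundle)
    if config.run_hazard_index and dataset.measurements:
        _stage_hazard(dataset, refs, config.profile, config.output_dir, bundle)

    summary_path = config.output_dir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    bundle.files["summary_txt"] = summary_path
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return bundle


def _stage_summary(dataset, refs, outdir: Path, bundle: ReportBundle) -> None:
    t0 = time.perf_counter()
    summaries = summarize_all(dataset)
    frame = pd.DataFrame(
        [
            {
                "pesticide": s.pesticide,
                "n_detect": s.n_detect,
                "mean_mg_kg": round_half_up(s.mean, 3),
                "min_mg_kg": round_half_up(s.min, 3),
                "max_mg_kg": round_half_up(s.max, 3),
                "total_mg_kg": round_half_up(s.total, 3),
            }
            for s in summaries.values()
        ]
    )
    _write(frame, outdir / "summary.csv")
    bundle.files["summary"] = outdir / "summary.csv"
    if dataset.measurements:
        class_shares, pesticide_shares = class_composition(dataset, refs)
        comp = pd.DataFrame(
            [
                {"level": "class", "name": name, "share_percent": round_half_up(v, 2)}
                for name, v in sorted(class_shares.items())
            ]
            + [
                {"level": "pesticide", "name": name, "share_percent": round_half_up(v, 2)}
                for name, v in sorted(pesticide_shares.items())
            ]
        )
        _write(comp, outdir / "composition.csv")
        bundle.files["composition"] = outdir / "composition.csv"
    dist = residue_count_distribution(dataset)
    _write(
        pd.DataFrame(
            [
                {"n_residues": k, "percent_of_samples": round_half_up(v, 0)}
                for k, v in dist.items()
            ]
        ),
        outdir / "residue_counts.csv",
    )
    bundle.files["residue_counts"] = outdir / "residue_counts.csv"
    logger.info("stage summary: %.2fs", time.perf_counter() - t0)


def _stage_compliance(dataset, refs, outdir: Path, bundle: ReportBundle) -> None:
    t0 = time.perf_counter()
    records, non_compliant = assess_compliance(dataset, refs)
    frame = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "pesticide": r.pesticide,
                "concentration_mg_kg": r.concentration,
                "mrl_mg_kg": r.mrl,
                "percent_mrl": int(round_half_up(r.percent_mrl, 0)),
                "exceeds": r.exceeds,
            }
            for r in records
        ]
    )
    _write(frame, outdir / "compliance.csv")
    bundle.files["compliance"] = outdir / "compliance.csv"
    bundle.summary_lines.append(
        "non-compliant samples: " + (", ".join(non_compliant) if non_compliant else "none")
    )
    logger.info("stage compliance: %.2fs", time.perf_counter() - t0)


def _stage_acute(dataset, refs, profile, outdir: Path, bundle: ReportBundle) -> None:
    t0 = time.perf_counter()
    results, not_assessable = assess_acute(dataset, refs, profile)
    rows = [
        {
            "pesticide": r.pesticide,
            "hr_mg_kg": r.hr,
            "iesti_mg_kg_bw": r.iesti,
            "percent_arfd": _fmt_pct(r.percent_arfd),
            "case_used": r.case_used,
        }
        for r in results
    ] + [
        {
            "pesticide": name,
            "hr_mg_kg": max(
                m.concentration for m in dataset.measurements if m.pesticide == name
            ),
            "iesti_mg_kg_bw": NOT_APPLICABLE,
            "percent_arfd": NOT_APPLICABLE,
            "case_used": NOT_APPLICABLE,
        }
        for name in not_assessable
    ]
    _write(pd.DataFrame(rows), outdir / "acute.csv")
    bundle.files["acute"] = outdir / "acute.csv"
    if results:
        worst = max(results, key=lambda r: r.percent_arfd)
        bundle.summary_lines.append(
            f"max %ARfD: {worst.pesticide} "
            f"({round_half_up(worst.percent_arfd, 2)}% of ARfD, HR {worst.hr} mg/kg)"
        )
    if not_assessable:
        bundle.summary_lines.append(
            "ARfD not applicable: " + ", ".join(sorted(not_assessable))
        )
    logger.info("stage acute: %.2fs", time.perf_counter() - t0)


def _stage_chronic(dataset, refs, profile, outdir: Path, bundle: ReportBundle) -> None:
    t0 = time.perf_counter()
    results, not_assessable = assess_chronic(dataset, refs, profile)
    rows = [
        {
            "pesticide": r.pesticide,
            "apr_mg_kg": round_half_up(r.apr, 3),
            "nedi_mg_kg_bw_day": r.nedi,
            "percent_adi": _fmt_pct(r.percent_adi, 3),
        }
        for r in results
    ] + [
        {
            "pesticide": name,
            "apr_mg_kg": NOT_APPLICABLE,
            "nedi_mg_kg_bw_day": NOT_APPLICABLE,
            "percent_adi": NOT_APPLICABLE,
        }
        for name in not_assessable
    ]
    _write(pd.DataFrame(rows), outdir / "chronic.csv")
    bundle.files["chronic"] = outdir / "chronic.csv"
    if results:
        worst = max(results, key=lambda r: r.percent_adi)
        bundle.summary_lines.append(
            f"max %ADI: {worst.pesticide} ({round_half_up(worst.percent_adi, 3)}% of ADI)"
        )
    if not_assessable:
        bundle.summary_lines.append("ADI not applicable: " + ", ".join(sorted(not_assessable)))
    logger.info("stage chronic: %.2fs", time.perf_counter() - t0)


def _stage_hazard(dataset, refs, profile, outdir: Path, bundle: ReportBundle) -> None:
    t0 = time.perf_counter()
    rows = []
    for sample_id in dataset.sample_ids:
        hi, excluded = hazard_index(sample_id, dataset, refs, profile)
        rows.append(
            {
                "sample_id": sample_id,
                "hi_percent": round_half_up(hi, 2),
                "n_excluded": len(excluded),
            }
        )
    _write(pd.DataFrame(rows), outdir / "hazard_index.csv")
    bundle.files["hazard_index"] = outdir / "hazard_index.csv"
    logger.info("stage hazard index: %.2fs", time.perf_counter() - t0)


def default_pipeline_config(output_dir: Path, **overrides) -> PipelineConfig:
    """Config pointing at the bundled campaign with the NL-toddler profile."""
    params = dict(
        residue_path=bundled_path("residues.csv"),
        reference_path=bundled_path("references.csv"),
        output_dir=Path(output_dir),
        profile=load_consumption_profile(),
        n_samples_total=83,
    )
    params.update(overrides)
    return PipelineConfig(**params)
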