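"""End-to-end pipeline: simulate → extract → norms → score → calibrate →
validate, with a YAML-backed configuration and structured outputs."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .errors import InvalidArgumentError, OpiScoreError
from .opi import OpiConfig, extract_opis
from .rasch import calibrate, flag_fit
from .scoring import RubricConfig, fit_expert_norms, score_cohort
from .synth import make_reference_cohort
from .validity import (
    banding_check,
    build_wright_map,
    construct_alignment_rho,
    fairness_dif,
    item_ability_biserial,
)

log = logging.getLogger("opiscore")

LEVEL_RANK = {"completion": 1, "safety": 2, "economy": 3, "optimized": 4}


@dataclass
class PipelineConfig:
    """Everything a run needs; mirrors the YAML config file."""

    seed: int = 0
    duration_s: float = 60.0
    rate_hz: float = 50.0
    beyond_norm_fraction: float = 0.4
    opi: OpiConfig = field(default_factory=OpiConfig)
    rubric: RubricConfig = field(default_factory=RubricConfig)
    n_quadrature: int = 41
    tol: float = 1e-5
    max_iter: int = 500
    fit_lower: float = 0.7
    fit_upper: float = 1.3
    fairness_groups: tuple[str, str] = ("female", "male")
    fairness_items: list[int] | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise InvalidArgumentError("duration_s and rate_hz must be positive")
        if not 0.0 <= self.beyond_norm_fraction <= 1.0:
            raise InvalidArgumentError("beyond_norm_fraction must lie in [0, 1]")
        if self.n_quadrature < 3 or self.max_iter < 1 or self.tol <= 0:
            raise InvalidArgumentError("invalid Rasch settings")
        if self.fit_lower >= self.fit_upper:
            raise InvalidArgumentError("fit_lower must be below fit_upper")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        opi = OpiConfig(**raw.pop("opi", {}))
        rubric_raw = raw.pop("rubric", {})
        if "opi_item_map" in rubric_raw:
            rubric_raw["opi_item_map"] = {
                int(k): v for k, v in rubric_raw["opi_item_map"].items()
            }
        rubric = RubricConfig(**rubric_raw)
        if "fairness_groups" in raw:
            raw["fairness_groups"] = tuple(raw["fairness_groups"])
        return cls(opi=opi, rubric=rubric, **raw)

    def echo(self) -> dict[str, Any]:
        d = asdict(self)
        d["rubric"]["opi_item_map"] = dict(self.rubric.opi_item_map)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except OpiScoreError as exc:
                raise OpiScoreError(f"[stage:{name}] {exc}") from exc
            return out

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute all stages on the reference cohort and write the report bundle.

    Returns the structured summary that is also written to ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict[str, Any]:
    log.info(
        "start version=%s python=%s seed=%d", __version__, sys.version.split()[0], config.seed
    )
    log.info("config=%s", json.dumps(config.echo(), default=str))

    cohort = _simulate(config)
    log.info("simulate: %d trainees, %d experts", len(cohort.trainees), len(cohort.experts))

    opi_trainee, opi_expert = _extract(config, cohort)
    log.info("extract: %d trainee rows, %d expert rows", len(opi_trainee), len(opi_expert))
    io.write_opi_csv(opi_trainee, outdir / "opi_trainees.csv")
    io.write_opi_csv(opi_expert, outdir / "opi_experts.csv")

    norms = fit_expert_norms(list(opi_expert.values()))
    norms.as_frame().to_csv(outdir / "expert_norms.csv")
    log.info("norms: fitted on %d experts", norms.n_experts)

    video = {r.subject_id: r.video for r in cohort.trainees}
    groups = {r.subject_id: r.group for r in cohort.trainees}
    io.write_outcomes_csv(video, outdir / "outcomes.csv", group=groups)
    opis = pd.DataFrame({sid: v.as_dict() for sid, v in opi_trainee.items()}).T
    opis.index.name = "subject_id"
    matrix = score_cohort(opis, video, norms, config.rubric, group=groups)
    io.write_score_csv(matrix, outdir / "score_matrix.csv")
    n_pass_video = int((matrix.gated_from == 0).sum())
    log.info(
        "score: %d subjects, %d passed all video items, %d gated",
        matrix.n_persons, n_pass_video, matrix.n_persons - n_pass_video,
    )

    fit = calibrate(
        matrix, n_quadrature=config.n_quadrature, tol=config.tol, max_iter=config.max_iter
    )
    flags = flag_fit(fit.infit_mnsq, config.fit_lower, config.fit_upper)
    items_df = pd.DataFrame(
        {
            "item": np.arange(1, matrix.n_items + 1),
            "delta": fit.delta,
            "delta_se": fit.delta_se,
            "infit_mnsq": fit.infit_mnsq,
            "outfit_mnsq": fit.outfit_mnsq,
            "flag": flags,
        }
    )
    items_df.to_csv(outdir / "calibration_items.csv", index=False, float_format="%.6g")
    persons_df = pd.DataFrame(
        {
            "subject_id": matrix.subject_ids,
            "theta_eap": fit.theta_eap,
            "psd_eap": fit.psd_eap,
            "theta_wle": fit.theta_wle,
            "se_wle": fit.se_wle,
        }
    )
    persons_df.to_csv(outdir / "calibration_persons.csv", index=False, float_format="%.6g")
    log.info(
        "calibrate: converged=%s iters=%d eap_rel=%.3f wle_rel=%.3f",
        fit.converged, fit.n_iter, fit.eap_reliability, fit.wle_reliability,
    )

    validity: dict[str, Any] = {}
    bis = item_ability_biserial(matrix, fit.theta_wle, levels=matrix.levels)
    validity["biserial_per_item"] = [
        None if np.isnan(v) else round(float(v), 6) for v in bis["per_item"]
    ]
    validity["level_mean_ability"] = bis.get("level_mean_ability")
    validity["level_order_monotone"] = bis.get("level_order_monotone")
    level_ranks = np.array(
        [LEVEL_RANK[config.rubric.level_of_item(i)] for i in range(1, matrix.n_items + 1)],
        dtype=float,
    )
    try:
        rho = construct_alignment_rho(level_ranks[fit.item_mask], fit.delta[fit.item_mask])
    except OpiScoreError:
        rho = None
    validity["construct_alignment_rho"] = rho
    wmap = build_wright_map(fit, config.rubric)
    validity["banding"] = banding_check(wmap)
    pd.DataFrame(wmap.item_locations, columns=["item", "level", "delta"]).to_csv(
        outdir / "wright_items.csv", index=False, float_format="%.6g"
    )
    pd.DataFrame({"theta": wmap.person_locations}).to_csv(
        outdir / "wright_persons.csv", index=False, float_format="%.6g"
    )
    fairness_summary = None
    try:
        fairness = fairness_dif(
            matrix,
            config.fairness_groups,
            item_subset=config.fairness_items,
            n_quadrature=config.n_quadrature,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        fairness_summary = {
            "item_subset": fairness.item_subset,
            "dropped_items": fairness.dropped_items,
            "pearson_r": round(fairness.pearson_r, 6),
            "score_profile_r": fairness.score_profile_r,
            "ci_overlap": [bool(v) for v in fairness.ci_overlap],
        }
    except OpiScoreError as exc:
        log.warning("fairness stage skipped: %s", exc)
    validity["fairness"] = fairness_summary
    log.info("validate: rho=%s fairness=%s", rho, bool(fairness_summary))

    level_counts = pd.Series(matrix.levels).value_counts().to_dict()
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "n_trainees_scored": matrix.n_persons,
        "n_experts": norms.n_experts,
        "n_passed_all_video_items": n_pass_video,
        "n_gated": matrix.n_persons - n_pass_video,
        "level_counts": {str(k): int(v) for k, v in level_counts.items()},
        "eap_reliability": round(float(fit.eap_reliability), 6),
        "wle_reliability": round(float(fit.wle_reliability), 6),
        "flagged_items": [int(i + 1) for i, f in enumerate(flags) if f not in ("ok",)],
        "validity": validity,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    log.info("done")
    return summary


@_stage("simulate")
def _simulate(config: PipelineConfig):
    return make_reference_cohort(
        seed=config.seed,
        duration_s=config.duration_s,
        rate_hz=config.rate_hz,
        beyond_norm_fraction=config.beyond_norm_fraction,
    )


@_stage("extract")
def _extract(config: PipelineConfig, cohort):
    opi_trainee = {
        r.subject_id: extract_opis(r.stream, r.events, config.opi) for r in cohort.trainees
    }
    opi_expert = {
        r.subject_id: extract_opis(r.stream, r.events, config.opi) for r in cohort.experts
    }
    return opi_trainee, opi_expert
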