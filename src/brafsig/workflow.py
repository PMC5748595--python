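"""End-to-end workflow: synthesize -> prescreen -> LOOCV -> stability -> concordance.

``run_workflow`` consumes a plain configuration mapping (usually loaded
from YAML), executes every stage with seeds derived from one master
seed, and writes a deterministic report bundle (JSON plus TSVs) to the
output directory.  In ``files`` mode the cohort is read from user
-supplied matrix/annotation/signature paths and only the LOOCV stage
runs; in ``synthetic`` mode the full pipeline is exercised on a
generated cohort.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centroid import build_templates, score_cohort, write_templates
from .concordance import apply_exclusions, concordance_report
from .errors import BrafSigError, ValidationError
from .io import (
    align_to_signature,
    read_annotations,
    read_matrix,
    read_signature,
    write_annotations,
    write_matrix,
)
from .simulate import (
    CohortSpec,
    FfpeNoiseSpec,
    degrade_to_ffpe,
    generate_cohort,
    generate_control_replicates,
    make_signature,
)
from .stability import assess_control, borderline_region, estimate_range
from .validate import cohort_composition, expected_specificity, prescreen_select, run_loocv

__all__ = ["default_config", "load_config", "run_workflow", "select_controls"]

# offsets added to the master seed, one per randomized stage
_SEED_COHORT = 0
_SEED_PRESCREEN = 101
_SEED_FFPE = 211
_SEED_CONTROLS = 307


def default_config(seed: int = 1) -> dict[str, Any]:
    """Baseline configuration: a 302-sample synthetic study."""
    return {
        "mode": "synthetic",
        "seed": int(seed),
        "metric": "pearson",
        "cohort": dataclasses.asdict(CohortSpec(n_samples=302, seed=int(seed))),
        "prescreen": {"enabled": False, "pool_size": 602, "k_top": 96, "k_random": 206},
        "ffpe_noise": {"degradation_sd": 0.35, "sampling_sd": 0.20},
        "control_noise": {"degradation_sd": 0.35, "sampling_sd": 0.0},
        "n_control_reps": 40,
        "exclusions": {"min_tumor_pct": 30.0, "min_signal": None},
        "inputs": {},
    }


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config file on top of the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ValidationError("config file must contain a mapping")
    cfg = default_config(int(user.get("seed", 1)))
    for key, value in user.items():
        if key in cfg and isinstance(cfg[key], dict) and isinstance(value, Mapping):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def select_controls(scores: pd.Series, labels: np.ndarray) -> tuple[str, str]:
    """Pick one unambiguous control per class from cohort scores.

    Returns (mutant control id, wild-type control id): the sequenced
    mutant with the highest signature score and the sequenced wild-type
    with the lowest, i.e. the clearest representative of each class —
    mirroring how a QC lab chooses technical control samples.
    """
    mut = scores[np.asarray(labels) == "mutated"]
    wt = scores[np.asarray(labels) == "wildtype"]
    if mut.empty or wt.empty:
        raise ValidationError("both classes are required to select controls")
    return str(mut.idxmax()), str(wt.idxmin())


def _cohort_from_config(cfg: Mapping[str, Any]):
    mode = cfg.get("mode", "synthetic")
    if mode == "files":
        inputs = cfg.get("inputs") or {}
        for field in ("matrix", "annotations", "signature"):
            if not inputs.get(field):
                raise ValidationError(f"config field inputs.{field} is required in files mode")
        matrix = read_matrix(inputs["matrix"])
        annotations = read_annotations(inputs["annotations"])
        signature = read_signature(inputs["signature"])
        return matrix, annotations, signature
    if mode != "synthetic":
        raise ValidationError(f"config field mode must be 'synthetic' or 'files', got {mode!r}")

    seed = int(cfg["seed"])
    cohort_cfg = dict(cfg["cohort"])
    cohort_cfg["seed"] = seed + _SEED_COHORT
    prescreen = cfg.get("prescreen") or {}
    signature = make_signature(int(cohort_cfg.get("n_signature_genes", 58)))
    if prescreen.get("enabled"):
        pool_cfg = dict(cohort_cfg, n_samples=int(prescreen["pool_size"]))
        pool, pool_ann, _ = generate_cohort(CohortSpec(**pool_cfg))
        pool_sig = align_to_signature(pool, signature)
        templates = build_templates(pool_sig, pool_ann["braf_status"].to_numpy())
        scored = score_cohort(pool_sig, templates, 0.0, cfg.get("metric", "pearson"))
        scores = pd.Series(scored.score_values, index=pool.sample_ids)
        k_top, k_random = int(prescreen["k_top"]), int(prescreen["k_random"])
        selected = prescreen_select(scores, k_top, k_random, seed + _SEED_PRESCREEN)
        matrix = pool.subset_samples(selected)
        annotations = pool_ann.set_index("sample_id").loc[selected].reset_index()
        annotations["cohort_tag"] = ["prescreen"] * k_top + ["random"] * k_random
        return matrix, annotations, signature
    matrix, annotations, _ = generate_cohort(CohortSpec(**cohort_cfg))
    return matrix, annotations, signature


def run_workflow(cfg: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute the configured workflow and write the report bundle.

    Returns the report dictionary; raises :class:`BrafSigError` (with
    stage context) on any stage failure.  Output is deterministic for a
    fixed configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 1))
    metric = cfg.get("metric", "pearson")
    report: dict[str, Any] = {"version": __version__, "config": _jsonable(cfg)}

    matrix, annotations, signature = _cohort_from_config(cfg)
    aligned = align_to_signature(matrix, signature)
    labels = annotations.set_index("sample_id").loc[aligned.sample_ids, "braf_status"].to_numpy()

    # LOOCV performance and threshold
    loocv = run_loocv(aligned, labels, metric)
    conf = loocv.confusion
    report["loocv"] = {
        "threshold": loocv.threshold,
        **conf.as_dict(),
        "expected_specificity": expected_specificity(conf.tp + conf.fn, conf.tn + conf.fp),
    }
    report["composition"] = (
        cohort_composition(annotations).reset_index().to_dict(orient="records")
    )
    templates = build_templates(aligned, labels)
    write_templates(templates, out / "templates.tsv")
    loocv.scores.rename("score").to_frame().assign(
        call=np.where(loocv.scores > loocv.threshold, "mutation_like", "wildtype_like")
    ).to_csv(out / "loocv_scores.tsv", sep="\t", index_label="sample_id", lineterminator="\n")
    write_matrix(matrix, out / "matrix.tsv")
    write_annotations(annotations, out / "annotations.tsv")

    if cfg.get("mode", "synthetic") != "synthetic":
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return report

    # stability QC on technical control replicates
    dist = estimate_range(loocv.scores.to_numpy())
    mut_ctrl, wt_ctrl = select_controls(loocv.scores, labels)
    ctrl_noise = FfpeNoiseSpec(**cfg["control_noise"], seed=seed + _SEED_CONTROLS)
    n_reps = int(cfg.get("n_control_reps", 40))
    chart_rows, control_reports, control_sds = [], [], []
    for offset, (sid, cls) in enumerate(
        ((mut_ctrl, "mutation_like"), (wt_ctrl, "wildtype_like"))
    ):
        noise = dataclasses.replace(ctrl_noise, seed=ctrl_noise.seed + offset)
        reps = generate_control_replicates(aligned.data[sid], n_reps, noise, signature)
        scored = score_cohort(reps, templates, loocv.threshold, metric)
        sr = assess_control(
            scored.score_values, dist.range_width, cls, loocv.threshold, control_id=sid
        )
        control_reports.append(sr)
        control_sds.append(sr.sd)
        for i, (score, call) in enumerate(zip(scored.score_values, scored.calls), start=1):
            chart_rows.append({"control_id": sid, "replicate": i, "score": score, "call": call})
    pd.DataFrame(chart_rows).to_csv(out / "control_chart.tsv", sep="\t", index=False, lineterminator="\n")
    report["stability"] = {
        "range_low": dist.range_low,
        "range_high": dist.range_high,
        "range_width": dist.range_width,
        "range_conservative": dist.conservative,
        "controls": [dataclasses.asdict(sr) for sr in control_reports],
    }
    region = borderline_region(loocv.threshold, control_sds)
    report["borderline_region"] = dataclasses.asdict(region)

    # paired fresh-frozen vs FFPE concordance
    ffpe_noise = FfpeNoiseSpec(**cfg["ffpe_noise"], seed=seed + _SEED_FFPE)
    ffpe = degrade_to_ffpe(aligned, ffpe_noise, signature)
    ff_scored = score_cohort(aligned, templates, loocv.threshold, metric)
    ffpe_scored = score_cohort(ffpe, templates, loocv.threshold, metric)
    pairs = pd.DataFrame(
        {
            "sample_id": aligned.sample_ids,
            "ff_score": ff_scored.score_values,
            "ffpe_score": ffpe_scored.score_values,
        }
    )
    ann_sig = annotations.copy()
    ann_sig["signal"] = ffpe.values.mean(axis=0)
    excl_cfg = cfg.get("exclusions") or {}
    min_signal = excl_cfg.get("min_signal")
    kept, tally = apply_exclusions(
        pairs,
        ann_sig,
        min_tumor_pct=float(excl_cfg.get("min_tumor_pct", 30.0)),
        min_signal=float("-inf") if min_signal is None else float(min_signal),
    )
    conc = concordance_report(kept, loocv.threshold, loocv.threshold, region, tally)
    report["concordance"] = conc.as_dict()
    conc.pairs.to_csv(out / "paired_scores.tsv", sep="\t", index=False, lineterminator="\n")

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
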