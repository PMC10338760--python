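"""End-to-end orchestration of the visibility study design at desk scale.

One run executes: cohort generation (phantoms) or ingestion (manifest) ->
visibility scoring -> pre-selection (continuity, location, visibility band)
-> train/test split -> per-arm segmentation -> GTV metrics -> CTV expansion
of clinical-truth and predicted GTVs -> CTV metrics -> independent t-test
between the two model arms on each test set -> report.

The "clinical" GTV in desk-scale runs is the phantom ground-truth mask and
the "autocontour" is the segmenter output, mapping the study's clinical-vs-
auto comparison onto truth-vs-baseline.  Each model arm "trains" by fitting
the baseline's HU band on its own training cases.  With the deterministic
baseline a fixed seed reproduces the report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baseline import BaselineSegmenter, fit_hu_band, run_segmenter_over_cohort
from .core import CasePaths, read_manifest, read_mask, read_volume
from .ctv import MarginSpec, expand_gtv_to_ctv
from .metrics import (
    CohortMetricSummary,
    compare_masks,
    independent_t_test,
    summarize_cohort,
)
from .phantom import PhantomSpec, generate_cohort
from .preselect import (
    CohortEntry,
    PreselectionCriteria,
    build_experiment_arms,
    preselect,
    split_cohort,
)
from .visibility import compute_visibility_metrics
from .preselect import check_continuity, check_location

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "write_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegimeConfig:
    """One phantom regime: how many cases and which generator overrides."""

    count: int
    delta_hu: float = -40.0
    sigma_hu: float = 5.0
    n_components: int = 1
    in_fossa: bool = True


@dataclass(frozen=True)
class PhantomCohortConfig:
    regimes: tuple[RegimeConfig, ...] = (
        RegimeConfig(count=20, delta_hu=-40.0, sigma_hu=5.0),
        RegimeConfig(count=10, delta_hu=0.0, sigma_hu=5.0),
    )
    shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    cavity_radius_mm: float = 8.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serializable run description; a run is reproducible from
    config + seed (the deterministic baseline has no other randomness)."""

    out_dir: str
    seed: int = 0
    phantom: PhantomCohortConfig | None = field(default_factory=PhantomCohortConfig)
    manifest: str | None = None
    criteria: PreselectionCriteria = field(default_factory=PreselectionCriteria)
    margin: MarginSpec = field(default_factory=MarginSpec)
    train_fraction: float = 0.8
    min_component_mm3: float = 100.0
    region_structure: str = "posterior_fossa"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "ExperimentConfig":
        payload = dict(payload)
        if payload.get("phantom") is not None:
            ph = dict(payload["phantom"])
            ph["regimes"] = tuple(RegimeConfig(**dict(r)) for r in ph.get("regimes", ()))
            for key in ("shape", "spacing"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            payload["phantom"] = PhantomCohortConfig(**ph)
        if payload.get("criteria") is not None:
            crit = dict(payload["criteria"])
            for key in ("contrast_band", "cnr_band"):
                if key in crit:
                    crit[key] = tuple(crit[key])
            payload["criteria"] = PreselectionCriteria(**crit)
        if payload.get("margin") is not None:
            payload["margin"] = MarginSpec(**dict(payload["margin"]))
        return cls(**payload)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    per_case: pd.DataFrame
    arm_summaries: dict[tuple[str, str, str], CohortMetricSummary]
    removal_counts: dict[str, int]
    visibility: pd.DataFrame
    t_tests: pd.DataFrame
    provenance: dict


MODELS = ("model1_full_training", "model2_preselected_training")


def _load_case(case: CasePaths):
    volume = read_volume(case.image)
    masks = {name: read_mask(p, volume, name) for name, p in case.structures.items()}
    return volume, masks


def _cohort_cases(config: ExperimentConfig, out_dir: Path) -> list[CasePaths]:
    if config.manifest is not None:
        return read_manifest(config.manifest)
    if config.phantom is None:
        raise ValueError("config must provide either a phantom cohort or a manifest")
    ph = config.phantom
    regimes = [
        (
            PhantomSpec(
                shape=ph.shape,
                spacing=ph.spacing,
                cavity_radius_mm=ph.cavity_radius_mm,
                delta_hu=r.delta_hu,
                sigma_hu=r.sigma_hu,
                n_components=r.n_components,
                in_fossa=r.in_fossa,
            ),
            r.count,
        )
        for r in ph.regimes
    ]
    cases, _ = generate_cohort(regimes, out_dir / "cohort", seed=config.seed)
    return cases


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full 2x2 study design; see the module docstring."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("stage: cohort")
    cases = _cohort_cases(config, out_dir)
    case_by_id = {c.case_id: c for c in cases}

    log.info("stage: visibility + curation flags")
    entries: list[CohortEntry] = []
    vis_rows = []
    for case in cases:
        volume, masks = _load_case(case)
        gtv = masks["gtv"]
        metrics = compute_visibility_metrics(volume, gtv)
        entry = CohortEntry(
            case_id=case.case_id,
            metrics=metrics,
            continuous=check_continuity(gtv),
            in_fossa=check_location(
                gtv, masks[config.region_structure], config.criteria.min_fossa_fraction
            ),
        )
        entries.append(entry)
        vis_rows.append(
            {
                "case_id": case.case_id,
                "n_roi": metrics.n_roi,
                "n_bkg": metrics.n_bkg,
                "mean_roi": metrics.mean_roi,
                "mean_bkg": metrics.mean_bkg,
                "std_bkg": metrics.std_bkg,
                "contrast": metrics.contrast,
                "cnr": metrics.cnr if metrics.cnr is not None else float("nan"),
                "continuous": entry.continuous,
                "in_fossa": entry.in_fossa,
            }
        )
    visibility_df = pd.DataFrame(vis_rows).sort_values("case_id").reset_index(drop=True)

    log.info("stage: split + pre-selection")
    train, test = split_cohort(entries, train_fraction=config.train_fraction, seed=config.seed)
    selection = preselect(entries, config.criteria)
    preselected_ids = {e.case_id for e in selection.kept}
    arms = build_experiment_arms(
        [e.case_id for e in train], [e.case_id for e in test], preselected_ids
    )
    full_test_ids = [e.case_id for e in test]
    pre_test_ids = [cid for cid in full_test_ids if cid in preselected_ids]
    if not pre_test_ids:
        raise RuntimeError(
            "pre-selection emptied the test set (criterion: "
            + ", ".join(k for k, v in selection.removal_counts.items() if v) + ")"
        )

    log.info("stage: per-arm segmentation + metrics")
    rows = []
    per_model_dsc: dict[tuple[str, str], list[float]] = {}
    for model in MODELS:
        train_ids = (
            [e.case_id for e in train]
            if model == "model1_full_training"
            else [e.case_id for e in train if e.case_id in preselected_ids]
        )
        if not train_ids:
            raise RuntimeError(f"empty training set for {model}")
        fit_data = []
        for cid in train_ids:
            volume, masks = _load_case(case_by_id[cid])
            fit_data.append((volume, masks["gtv"]))
        band = fit_hu_band(fit_data)
        log.info("%s: fitted HU band [%.1f, %.1f] from %d cases", model, *band, len(train_ids))
        segmenter = BaselineSegmenter(hu_band=band, min_component_mm3=config.min_component_mm3)
        pred_paths, failures = run_segmenter_over_cohort(
            segmenter,
            [case_by_id[cid] for cid in full_test_ids],
            out_dir / "predictions" / model,
            region_structure=config.region_structure,
        )
        for cid in full_test_ids:
            volume, masks = _load_case(case_by_id[cid])
            truth_gtv = masks["gtv"]
            pred_gtv = read_mask(pred_paths[cid], volume, "prediction") if cid in pred_paths else None
            in_pre = cid in preselected_ids
            if pred_gtv is None:
                continue
            gtv_cmp = compare_masks(pred_gtv, truth_gtv, cid, "gtv")
            rows.append({"model": model, "case_id": cid, "structure": "gtv",
                         "in_preselected_test": in_pre, **_metric_cols(gtv_cmp)})
            truth_ctv = expand_gtv_to_ctv(truth_gtv, masks["brain"], masks.get("brainstem"), config.margin)
            if pred_gtv.is_empty():
                ctv_cmp = compare_masks(pred_gtv, truth_ctv, cid, "ctv")  # total miss
            else:
                pred_ctv = expand_gtv_to_ctv(pred_gtv, masks["brain"], masks.get("brainstem"), config.margin)
                ctv_cmp = compare_masks(pred_ctv, truth_ctv, cid, "ctv")
            rows.append({"model": model, "case_id": cid, "structure": "ctv",
                         "in_preselected_test": in_pre, **_metric_cols(ctv_cmp)})
            per_model_dsc.setdefault((model, "full_test"), []).append(gtv_cmp.dsc)
            if in_pre:
                per_model_dsc.setdefault((model, "preselected_test"), []).append(gtv_cmp.dsc)
        if failures:
            log.warning("%s: %d segmentation failures: %s", model, len(failures), failures)

    per_case = pd.DataFrame(rows).sort_values(["model", "structure", "case_id"]).reset_index(drop=True)

    log.info("stage: summaries + t-tests")
    arm_summaries: dict[tuple[str, str, str], CohortMetricSummary] = {}
    for arm in arms:
        for structure in ("gtv", "ctv"):
            sub = per_case[
                (per_case.model == arm.model)
                & (per_case.structure == structure)
                & per_case.case_id.isin(arm.test_ids)
            ]
            comps = [
                compare_row_to_comparison(r) for r in sub.itertuples(index=False)
            ]
            if comps:
                arm_summaries[(arm.model, arm.test_set, structure)] = summarize_cohort(comps)

    t_rows = []
    for test_name in ("full_test", "preselected_test"):
        x = per_model_dsc.get((MODELS[0], test_name), [])
        y = per_model_dsc.get((MODELS[1], test_name), [])
        if len(x) >= 2 and len(y) >= 2:
            t, p, sig = independent_t_test(x, y)
            t_rows.append({"test_set": test_name, "metric": "gtv_dsc", "t": t, "p": p,
                           "significant_p05": sig, "n1": len(x), "n2": len(y)})
    t_tests = pd.DataFrame(t_rows)

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_cases": len(cases),
        "n_preselected": len(preselected_ids),
        "removal_counts": selection.removal_counts,
        "full_test_ids": full_test_ids,
        "preselected_test_ids": pre_test_ids,
    }
    return ExperimentReport(
        per_case=per_case,
        arm_summaries=arm_summaries,
        removal_counts=selection.removal_counts,
        visibility=visibility_df,
        t_tests=t_tests,
        provenance=provenance,
    )


def _metric_cols(cmp) -> dict:
    return {
        "dsc": cmp.dsc,
        "hd_mm": cmp.hd_mm,
        "msd_mm": cmp.msd_mm,
        "precision": cmp.precision,
        "recall": cmp.recall,
    }


def compare_row_to_comparison(row):
    from .metrics import ContourComparison

    return ContourComparison(
        case_id=row.case_id,
        structure=row.structure,
        dsc=row.dsc,
        hd_mm=row.hd_mm,
        msd_mm=row.msd_mm,
        precision=row.precision,
        recall=row.recall,
    )


def write_report(report: ExperimentReport, out_dir) -> dict[str, Path]:
    """Write per-case CSV, per-arm summary CSV, visibility/removal tables,
    t-test table, a JSON provenance block and a human-readable summary.

    Floats are written at fixed precision so identical reports serialize to
    identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(df: pd.DataFrame, name: str) -> None:
        p = out_dir / name
        df.to_csv(p, index=False, float_format="%.6f", lineterminator="\n")
        paths[name] = p

    save(report.per_case, "per_case_metrics.csv")
    save(report.visibility, "visibility.csv")
    save(report.t_tests, "t_tests.csv")

    summary_rows = []
    for (model, test_set, structure), s in sorted(report.arm_summaries.items()):
        row = {"model": model, "test_set": test_set, "structure": structure, "n": s.n,
               "fraction_dsc_above_090": s.fraction_dsc_above_090}
        for m in s.mean:
            row[f"mean_{m}"] = s.mean[m]
            row[f"sd_{m}"] = s.sd[m]
        summary_rows.append(row)
    save(pd.DataFrame(summary_rows), "arm_summaries.csv")

    removal = pd.DataFrame(
        [{"criterion": k, "removed": v} for k, v in report.removal_counts.items()]
    )
    save(removal, "removal_counts.csv")

    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(report.provenance, indent=2, sort_keys=True))
    paths["provenance.json"] = prov_path

    lines = ["Experiment report", "=================", ""]
    lines.append(f"cases: {report.provenance['n_cases']}  "
                 f"pre-selected: {report.provenance['n_preselected']}")
    lines.append(f"removals by criterion: {report.removal_counts}")
    lines.append("")
    for (model, test_set, structure), s in sorted(report.arm_summaries.items()):
        lines.append(
            f"{model} / {test_set} / {structure.upper()}: "
            f"DSC {s.mean['dsc']:.3f} +/- {s.sd['dsc']:.3f} (n={s.n})"
        )
    if len(report.t_tests):
        lines.append("")
        for r in report.t_tests.itertuples(index=False):
            lines.append(
                f"t-test model1 vs model2 GTV DSC on {r.test_set}: "
                f"t={r.t:.3f} p={r.p:.4f} significant={bool(r.significant_p05)}"
            )
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    paths["summary.txt"] = out_dir / "summary.txt"
    return paths
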