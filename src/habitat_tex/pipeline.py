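"""End-to-end orchestration: simulate -> segment -> partition -> extract ->
train -> evaluate.

``run_all`` executes the whole protocol on synthetic training and
validation cohorts (the cohorts are generated with different scanner
gains and kept apart throughout: selection and model fitting never see a
validation row) and assembles the evaluation report — per region x
classifier: training ROC (both pooled cross-validated and refit-on-train
scores, labeled), validation ROC at the training-derived Youden
threshold, pairwise DeLong matrices, and a normality screen of the
selected features.  Every random draw descends from the single config
seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evalstats, kinetics, segment, synth, texture
from .model import RegionModel

__all__ = [
    "PipelineConfig",
    "REGIONS",
    "MODEL_KINDS",
    "build_feature_table",
    "evaluate_models",
    "run_all",
    "validate_inputs",
    "report_hash",
]

log = logging.getLogger("habitat_tex")

REGIONS = ("whole", "early", "moderate", "late")
MODEL_KINDS = ("dt", "svm")


@dataclass
class PipelineConfig:
    """Serializable configuration of one full run."""

    seed: int = 17
    scenario: str = "default"
    n_train_benign: int = 84
    n_train_malignant: int = 125
    n_val_benign: int = 40
    n_val_malignant: int = 50
    grid: tuple[int, int] = (128, 128)
    levels: int = 256
    wavelets: tuple[str, ...] = texture.WAVELETS
    folds: int = 10
    fcm: segment.FCMParams = field(default_factory=segment.FCMParams)
    val_intensity_scale: float = 1.08  # scanner-gain surrogate
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid)
        d["wavelets"] = list(self.wavelets)
        return d

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        fcm = segment.FCMParams(**{k: tuple(v) if k == "init_centroids" else v
                                   for k, v in raw.pop("fcm", {}).items()})
        if "grid" in raw:
            raw["grid"] = tuple(raw["grid"])
        if "wavelets" in raw:
            raw["wavelets"] = tuple(raw["wavelets"])
        return cls(fcm=fcm, **raw)


def _study_features(study, truth_mask, cfg: PipelineConfig):
    """Segment + partition + extract the four region vectors for one study."""
    seg = segment.segment_study(study, truth_mask=truth_mask, params=cfg.fcm)
    sub = kinetics.partition_study(study, seg.mask)
    r0, c0, r1, c1 = seg.qroi.box
    patch = seg.qroi.patch
    lesion = seg.mask[r0:r1, c0:c1]
    rows = {}
    for region in REGIONS:
        if region == "whole":
            m = lesion
        else:
            m = sub.zone_mask(region)[r0:r1, c0:c1] & lesion
        fv = texture.extract_all(patch, m, region=region,
                                 levels=cfg.levels, wavelets=cfg.wavelets)
        rows[region] = fv
    return rows, seg, sub


def build_feature_table(
    studies, truth: synth.CohortTruth, cfg: PipelineConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """One row per patient x region with the 467 canonical columns.

    Returns the table and a list of exclusion records (segmentation
    failures), mirroring the clinical exclusion bookkeeping.
    """
    names = texture.feature_names(cfg.wavelets)
    records, excluded = [], []
    for study, mask in zip(studies, truth.masks):
        try:
            rows, _, _ = _study_features(study, mask, cfg)
        except (segment.SegmentationFailure, segment.DegenerateROIError) as exc:
            excluded.append({"patient_id": study.patient_id, "reason": str(exc)})
            continue
        for region, fv in rows.items():
            rec = {"patient_id": study.patient_id, "region": region,
                   "label": study.label, "cohort": study.cohort,
                   "missing_zone": fv.is_missing}
            rec.update(zip(names, fv.values))
            records.append(rec)
    table = pd.DataFrame.from_records(records)
    return table, excluded


def _region_frames(table: pd.DataFrame, region: str, names: list[str]):
    """Training/validation slices for one region.

    Patients whose zone is empty are dropped (``missing_zone`` flag).
    Features that are undefined for any training patient of the region
    (e.g. no valid co-occurrence pair at a long offset inside a small
    zone) are removed from that region's model; validation patients
    still carrying an undefined value among the kept features are
    excluded from that zone's evaluation.
    """
    sel = table[(table.region == region) & (~table.missing_zone)]
    train = sel[sel.cohort == "training"]
    val = sel[sel.cohort == "validation"]
    finite_cols = [n for n in names if np.isfinite(train[n].to_numpy(float)).all()]

    def unpack(df):
        X = df[finite_cols].astype(float)
        X.index = df.patient_id.to_numpy()
        ok = np.isfinite(X.to_numpy()).all(axis=1)
        X = X.loc[ok]
        y = (df.label == "malignant").astype(int).to_numpy()[ok]
        return X, y

    return unpack(train), unpack(val)


def _roc_dict(r: evalstats.ROCResult, extra: dict | None = None) -> dict:
    d = {"auc": r.auc, "ci": [r.ci_low, r.ci_high], "se": r.se}
    if extra:
        d.update(extra)
    return d


def evaluate_models(table: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Train the 8 models (2 kinds x 4 regions) and build the report."""
    names = texture.feature_names(cfg.wavelets)
    ss = np.random.SeedSequence(cfg.seed).spawn(1)[0]
    model_seed = int(ss.generate_state(1)[0] % (2**31 - 1))

    models: dict[str, dict] = {}
    scores: dict[str, dict] = {}  # model -> cohort -> (ids, y, s)
    for region in REGIONS:
        (Xtr, ytr), (Xva, yva) = _region_frames(table, region, names)
        for kind in MODEL_KINDS:
            tag = f"{kind.upper()}_{region.capitalize()}"
            rm = RegionModel(kind=kind, folds=cfg.folds, random_state=model_seed)
            rm.fit(Xtr, ytr)
            tr_refit = rm.predict_scores(Xtr)
            va_scores = rm.predict_scores(Xva)
            op = evalstats.youden_metrics(tr_refit, ytr)
            entry = {
                "region": region,
                "kind": kind,
                "n_train": int(len(Xtr)),
                "n_validation": int(len(Xva)),
                "selected_features": rm.selected_features,
                "empty_selection": rm.empty_selection,
                "training_cv": _roc_dict(evalstats.auc_delong(rm.cv_scores_, ytr)),
                "training_refit": _roc_dict(evalstats.auc_delong(tr_refit, ytr), op),
                "validation": _roc_dict(
                    evalstats.auc_delong(va_scores, yva),
                    evalstats.metrics_at_threshold(va_scores, yva, op["threshold"]),
                ),
            }
            models[tag] = entry
            scores[tag] = {
                "training": (list(Xtr.index), ytr, tr_refit),
                "validation": (list(Xva.index), yva, va_scores),
            }

    if cfg.out_dir:
        roc_dir = Path(cfg.out_dir) / "roc"
        roc_dir.mkdir(parents=True, exist_ok=True)
        for tag, per_cohort in scores.items():
            for cohort, (_, y, s) in per_cohort.items():
                pts = evalstats.roc_points(s, y)
                pd.DataFrame(pts).to_csv(
                    roc_dir / f"{tag}_{cohort}.csv", index=False)

    # pairwise DeLong matrices on the patients common to each model pair
    delong = {}
    tags = list(models)
    for cohort in ("training", "validation"):
        mat = {a: {} for a in tags}
        for ia, a in enumerate(tags):
            for b in tags[ia:]:
                if a == b:
                    mat[a][b] = 1.0
                    continue
                ids_a, ya, sa = scores[a][cohort]
                ids_b, yb, sb = scores[b][cohort]
                common = [i for i in ids_a if i in set(ids_b)]
                if len(common) < 4:
                    p = float("nan")
                else:
                    ia_idx = [ids_a.index(i) for i in common]
                    ib_idx = [ids_b.index(i) for i in common]
                    p = evalstats.delong_test(
                        np.asarray(sa)[ia_idx], np.asarray(sb)[ib_idx],
                        np.asarray(ya)[ia_idx],
                    )
                mat[a][b] = p
                mat[b][a] = p
        delong[cohort] = mat

    # normality screen of the selected features (training rows)
    ks = {}
    for tag, entry in models.items():
        region = entry["region"]
        (Xtr, _), _ = _region_frames(table, region, names)
        ks[tag] = {}
        for feat in entry["selected_features"]:
            p, mode = evalstats.ks_normality(Xtr[feat].to_numpy())
            ks[tag][feat] = {"p": p, "mode": mode}

    return {"models": models, "delong": delong, "ks_normality": ks,
            "caveats": ["p-values are raw (no multiple-testing correction)"]}


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the full protocol and return the evaluation report."""
    children = np.random.SeedSequence(cfg.seed).spawn(2)
    seed_train = int(children[0].generate_state(1)[0] % (2**31 - 1))
    seed_val = int(children[1].generate_state(1)[0] % (2**31 - 1))

    log.info("generating cohorts (scenario=%s)", cfg.scenario)
    tr_studies, tr_truth = synth.generate_cohort(
        cfg.n_train_benign, cfg.n_train_malignant, cfg.scenario, seed_train,
        grid=cfg.grid, cohort="training")
    va_studies, va_truth = synth.generate_cohort(
        cfg.n_val_benign, cfg.n_val_malignant, cfg.scenario, seed_val,
        grid=cfg.grid, cohort="validation",
        intensity_scale=cfg.val_intensity_scale)

    log.info("segmenting + extracting features (%d studies)",
             len(tr_studies) + len(va_studies))
    t_train, excl_tr = build_feature_table(tr_studies, tr_truth, cfg)
    t_val, excl_va = build_feature_table(va_studies, va_truth, cfg)
    table = pd.concat([t_train, t_val], ignore_index=True)

    log.info("training models")
    report = evaluate_models(table, cfg)
    report["config"] = cfg.to_dict()
    report["excluded"] = {"training": excl_tr, "validation": excl_va}
    counts = table.groupby(["cohort", "region"]).missing_zone.agg(["count", "sum"])
    report["zone_exclusions"] = {
        f"{c}/{r}": {"n": int(n), "missing_zone": int(s)}
        for (c, r), (n, s) in counts.iterrows()
    }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "schema.json").write_text(
            json.dumps(texture.feature_names(cfg.wavelets), indent=0))
    return report


def report_hash(report: dict) -> str:
    """Stable content hash of a report (reproducibility check)."""
    blob = json.dumps(report, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def validate_inputs(directory: str | Path) -> tuple[list[dict], list[dict]]:
    """Check an input directory of patient bundles.

    Returns ``(manifest, problems)``: usable studies and excluded ones
    with reasons; problems are reported, never raised.
    """
    directory = Path(directory)
    manifest, problems = [], []
    for npz_path in sorted(directory.glob("*.npz")):
        pid = npz_path.stem
        try:
            with np.load(npz_path) as data:
                if "pre" not in data or "post" not in data:
                    problems.append({"patient_id": pid, "reason": "missing pre/post arrays"})
                    continue
                pre, post = data["pre"], data["post"]
            if post.ndim != 3 or post.shape[0] != synth.N_PHASES:
                problems.append({"patient_id": pid,
                                 "reason": f"expected {synth.N_PHASES} post phases, got {post.shape}"})
                continue
            if post.shape[1:] != pre.shape:
                problems.append({"patient_id": pid, "reason": "pre/post shape mismatch"})
                continue
            sidecar = npz_path.with_suffix(".json")
            if not sidecar.exists():
                problems.append({"patient_id": pid, "reason": "missing JSON sidecar"})
                continue
            try:
                meta = json.loads(sidecar.read_text())
            except json.JSONDecodeError:
                problems.append({"patient_id": pid, "reason": "corrupt JSON sidecar"})
                continue
            missing = [k for k in ("label", "cohort") if k not in meta]
            if missing:
                problems.append({"patient_id": pid,
                                 "reason": f"sidecar missing fields {missing}"})
                continue
            manifest.append({"patient_id": pid, "path": str(npz_path), **{
                k: meta[k] for k in ("label", "cohort")}})
        except Exception as exc:  # unreadable bundle
            problems.append({"patient_id": pid, "reason": f"unreadable: {exc}"})
    return manifest, problems
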