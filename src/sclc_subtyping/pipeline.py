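"""End-to-end discovery and validation pipelines.

``run_discovery`` chains the full analysis on one cohort: quantification
(iBAQ → FOT → imputation), clustering-feature selection, consensus NMF over a
range of cluster numbers, stability/prognosis selection of k, hazard-ordered
subtype naming, per-subtype signature derivation, classifier panel and
random-forest training, and the survival analyses (subtype KM + log-rank,
multivariate Cox, chemotherapy benefit in TNM II/III).  ``run_validation``
applies a trained classifier to an external cohort and repeats the survival
comparison on predicted labels.  Both are deterministic under a fixed config.
"""

from __future__ import annotations

import pickle
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .features import FeatureSet, select_classifier_candidates, select_clustering_features
from .nmf import ConsensusResult, KSelection, consensus_cluster, minmax_scale_rows, select_k
from .quantify import AbundanceMatrix, IntensityTable, compute_fot, compute_ibaq, impute_missing
from .signatures import (
    ClassifierModel,
    classifier_features,
    predict_subtypes,
    subtype_signatures,
    train_classifier,
)
from .survival import (
    chemo_benefit_analysis,
    cox_ph,
    km_estimate,
    logrank_test,
    subtype_names,
)

__all__ = [
    "PipelineConfig",
    "DiscoveryResult",
    "ValidationResult",
    "quantify_intensity",
    "run_discovery",
    "run_validation",
    "save_model",
    "load_model",
    "subtype_cox_table",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the discovery-analysis settings."""

    seed: int = 0
    top_n_clustering: int = 1100
    min_detect_clustering: float = 0.10
    cv_threshold: float = 1.9
    k_min: int = 2
    k_max: int = 6
    n_runs: int = 50
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    silhouette_min: float = 0.8
    min_class: int = 10
    prognostic_alpha: float = 0.01
    signature_fc_default: float = 3.0
    signature_fc_worst: float = 10.0
    signature_alpha: float = 0.05
    top_n_classifier: int = 500
    min_detect_classifier: float = 0.25
    classifier_fc_min: float = 1.5
    classifier_alpha: float = 0.05
    rf_trees: int = 500
    cv_folds: int = 10

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        for name in ("min_detect_clustering", "min_detect_classifier",
                     "signature_alpha", "classifier_alpha", "prognostic_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_runs < 1 or self.rf_trees < 1 or self.cv_folds < 2:
            raise ValueError("n_runs, rf_trees must be >= 1 and cv_folds >= 2")


@dataclass
class DiscoveryResult:
    abundance: AbundanceMatrix
    clustering_features: FeatureSet
    k_selection: KSelection
    subtype_labels: pd.Series | None  # named labels ("S-I", ...) per sample
    signature_sets: dict | None
    classifier: ClassifierModel | None
    survival_report: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


@dataclass
class ValidationResult:
    predictions: pd.DataFrame
    survival_report: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def quantify_intensity(intensity: IntensityTable) -> AbundanceMatrix:
    """iBAQ → FOT → per-sample missing-value imputation."""
    return impute_missing(compute_fot(compute_ibaq(intensity)))


def subtype_cox_table(clinical: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Design matrix for the multivariate Cox model.

    Subtype enters as indicator columns against the best-prognosis subtype;
    TNM stage is categorical with stage I as reference; VALG, gender,
    smoking, LNM and chemotherapy are binary; age is continuous.
    """
    X = pd.DataFrame(index=clinical.index)
    levels = sorted(labels.unique())
    for lev in levels[1:]:
        X[f"subtype_{lev}"] = (labels == lev).astype(float).to_numpy()
    for stage in ("II", "III", "IV"):
        col = (clinical["tnm_stage"] == stage).astype(float)
        if col.sum() > 0:
            X[f"tnm_{stage}"] = col
    X["valg_ES"] = (clinical["valg_stage"] == "ES").astype(float)
    X["chemotherapy"] = clinical["chemotherapy"].astype(float)
    X["age"] = clinical["age"].astype(float)
    X["gender_male"] = (clinical["gender"] == "male").astype(float)
    X["smoking"] = clinical["smoking"].astype(float)
    X["lnm"] = clinical["lnm"].astype(float)
    # drop covariates made constant (or collinear duplicates) by the cohort draw
    X = X.loc[:, X.nunique() > 1]
    X = X.T.drop_duplicates().T
    return X


def _survival_report(clinical: pd.DataFrame, labels: pd.Series) -> dict:
    times = clinical["os_years"].to_numpy(dtype=float)
    events = clinical["os_event"].to_numpy(dtype=bool)
    report: dict = {}
    report["km_by_subtype"] = {
        str(lev): km_estimate(times[labels == lev], events[labels == lev])
        for lev in sorted(labels.unique())
    }
    lr = logrank_test(times, events, labels.to_numpy())
    report["logrank"] = {"statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value}
    try:
        X = subtype_cox_table(clinical, labels)
        cox = cox_ph(times, events, X)
        report["cox"] = cox.summary()
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - diagnostics path
        report["cox_error"] = str(exc)
    report["chemo_benefit"] = chemo_benefit_analysis(clinical, labels.to_numpy())
    return report


def run_discovery(
    intensity: IntensityTable | None,
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
    abundance: AbundanceMatrix | None = None,
    outdir: str | Path | None = None,
) -> DiscoveryResult:
    """Execute the full discovery chain on one cohort.

    Provide either a raw ``intensity`` table or an already-quantified
    ``abundance`` matrix.  With ``outdir`` set, per-stage TSV/JSON outputs
    and a run manifest are written.  A cohort in which no k satisfies the
    stability and prognosis criteria yields a result with
    ``k_selection.valid == False`` and no downstream stages, not an error.
    """
    config = config or PipelineConfig()
    config.validate()
    t0 = time.time()
    timings: dict[str, float] = {}
    warnings: list[str] = []

    if abundance is None:
        if intensity is None:
            raise ValueError("provide an intensity table or an abundance matrix")
        abundance = quantify_intensity(intensity)
        sample_order = intensity.sample_ids
    else:
        sample_order = abundance.sample_ids
    if list(clinical["sample_id"]) != list(sample_order):
        raise ValueError("clinical table rows must match the sample columns in order")
    timings["quantify"] = time.time() - t0

    t = time.time()
    feats = select_clustering_features(
        abundance,
        top_n=config.top_n_clustering,
        min_detect_fraction=config.min_detect_clustering,
        cv_threshold=config.cv_threshold,
    )
    timings["feature_selection"] = time.time() - t

    t = time.time()
    V = minmax_scale_rows(abundance.fot.loc[feats.protein_ids].to_numpy(dtype=float))
    results: dict[int, ConsensusResult] = {}
    for k in range(config.k_min, config.k_max + 1):
        if k > min(V.shape):
            warnings.append(f"k={k} exceeds matrix rank bound; skipped")
            continue
        results[k] = consensus_cluster(
            V, k, n_runs=config.n_runs, base_seed=config.seed + 1000 * k,
            max_iter=config.nmf_max_iter, tol=config.nmf_tol,
        )
    selection = select_k(
        results, clinical,
        silhouette_min=config.silhouette_min,
        min_class=config.min_class,
        prognostic_alpha=config.prognostic_alpha,
    )
    timings["consensus_nmf"] = time.time() - t

    result = DiscoveryResult(
        abundance=abundance,
        clustering_features=feats,
        k_selection=selection,
        subtype_labels=None,
        signature_sets=None,
        classifier=None,
    )
    if not selection.valid:
        warnings.append("no k satisfied the stability and prognosis criteria")
        result.manifest = _manifest(config, timings, warnings)
        if outdir is not None:
            _write_outputs(result, clinical, Path(outdir), config)
        return result

    name_map = subtype_names(
        clinical["os_years"], clinical["os_event"], selection.labels
    )
    labels = pd.Series(
        [name_map[lab] for lab in selection.labels], index=clinical.index, name="subtype"
    )
    result.subtype_labels = labels

    t = time.time()
    worst = sorted(labels.unique())[-1]
    fc_thresholds = {
        lev: (config.signature_fc_worst if lev == worst else config.signature_fc_default)
        for lev in labels.unique()
    }
    result.signature_sets = subtype_signatures(
        abundance, labels.to_numpy(), fc_thresholds, alpha=config.signature_alpha
    )
    timings["signatures"] = time.time() - t

    t = time.time()
    candidates = select_classifier_candidates(
        abundance, top_n=config.top_n_classifier,
        min_detect_fraction=config.min_detect_classifier,
    )
    panel = classifier_features(
        abundance, labels.to_numpy(), candidates,
        fc_min=config.classifier_fc_min, alpha=config.classifier_alpha,
    )
    if not panel:
        warnings.append("classifier panel empty; classifier stage skipped")
    else:
        result.classifier = train_classifier(
            abundance, labels.to_numpy(), panel, seed=config.seed,
            n_trees=config.rf_trees, n_folds=min(config.cv_folds, len(labels)),
        )
    timings["classifier"] = time.time() - t

    t = time.time()
    result.survival_report = _survival_report(clinical, labels)
    timings["survival"] = time.time() - t

    result.manifest = _manifest(config, timings, warnings)
    if outdir is not None:
        _write_outputs(result, clinical, Path(outdir), config)
    return result


def run_validation(
    model: ClassifierModel,
    abundance: AbundanceMatrix,
    clinical: pd.DataFrame | None = None,
) -> ValidationResult:
    """Predict subtypes for an external cohort and compare their survival."""
    preds = predict_subtypes(model, abundance)
    warnings: list[str] = []
    report: dict = {}
    if clinical is not None:
        if list(clinical["sample_id"]) != list(preds.index):
            raise ValueError("clinical rows must match predicted samples in order")
        labels = pd.Series(preds["predicted"].to_numpy(), index=clinical.index)
        if len(labels) < 2 or labels.nunique() < 2:
            warnings.append("survival stage skipped: fewer than two predicted groups")
        else:
            times = clinical["os_years"].to_numpy(dtype=float)
            events = clinical["os_event"].to_numpy(dtype=bool)
            lr = logrank_test(times, events, labels.to_numpy())
            report["logrank"] = {
                "statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value
            }
            report["km_by_subtype"] = {
                str(lev): km_estimate(times[labels == lev], events[labels == lev])
                for lev in sorted(labels.unique())
            }
    return ValidationResult(predictions=preds, survival_report=report, warnings=warnings)


def save_model(model: ClassifierModel, path, training_digest: str = "") -> None:
    """Serialise a trained classifier with format version and provenance."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "model": model,
        "training_digest": training_digest,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> ClassifierModel:
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupted model archive: {path}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"not a classifier archive: {path}")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return payload["model"]


def _manifest(config: PipelineConfig, timings: dict, warnings: list[str]) -> dict:
    from . import __version__

    return {
        "package_version": __version__,
        "config": asdict(config),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "warnings": warnings,
    }


def _write_outputs(
    result: DiscoveryResult, clinical: pd.DataFrame, outdir: Path,
    config: PipelineConfig,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_abundance(result.abundance, outdir / "abundance.tsv")
    pd.DataFrame(
        {"protein_id": result.clustering_features.protein_ids, "stage": "clustering"}
    ).to_csv(outdir / "clustering_features.tsv", sep="\t", index=False)
    result.clustering_features.per_protein_stats.to_csv(
        outdir / "clustering_feature_stats.tsv", sep="\t", index_label="protein_id"
    )
    result.k_selection.report.to_csv(outdir / "k_selection.tsv", sep="\t")
    for k, res in result.k_selection.results.items():
        pd.DataFrame(
            res.consensus, index=result.abundance.sample_ids,
            columns=result.abundance.sample_ids,
        ).to_csv(outdir / f"consensus_k{k}.tsv", sep="\t", index_label="sample_id")
    if result.subtype_labels is not None:
        pd.DataFrame(
            {"sample_id": result.abundance.sample_ids,
             "subtype": result.subtype_labels.to_numpy()}
        ).to_csv(outdir / "subtype_labels.tsv", sep="\t", index=False)
    if result.signature_sets is not None:
        rows = []
        for subtype, sig in result.signature_sets.items():
            for pid, row in sig.entries.iterrows():
                rows.append((subtype, pid, row["fold_change"], row["p_value"],
                             row["adjusted_p"]))
        pd.DataFrame(
            rows, columns=["subtype", "protein_id", "fold_change", "p_value",
                           "adjusted_p"]
        ).to_csv(outdir / "signatures.tsv", sep="\t", index=False)
    if result.classifier is not None:
        save_model(result.classifier, outdir / "classifier_model.pkl")
    stats: dict = {"manifest": result.manifest}
    if "logrank" in result.survival_report:
        stats["logrank"] = result.survival_report["logrank"]
    if "cox" in result.survival_report:
        stats["cox"] = result.survival_report["cox"].to_dict(orient="index")
    if "chemo_benefit" in result.survival_report:
        stats["chemo_benefit"] = (
            result.survival_report["chemo_benefit"].reset_index()
            .to_dict(orient="records")
        )
    sio.write_json(stats, outdir / "stats.json")
    config.to_yaml(outdir / "config_used.yaml")
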