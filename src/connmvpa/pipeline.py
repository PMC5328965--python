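"""End-to-end orchestration: manifest in, full classification report out.

The full route is preprocess (when the manifest points at raw time
series) -> connectivity features -> LOOCV with nested Kendall-tau
selection -> consensus connections and region weights -> whole-pipeline
permutation test. A feature-level manifest skips the first two stages.
Every run emits a machine-readable log with versions, seeds, parameters
and the preprocessing order in effect, sufficient to reproduce the run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import CVResult, SvmConfig, loocv
from .connectivity import correlation_matrix, vectorize_upper
from .features import (
    ConsensusSet,
    LabeledStudy,
    PairSignCache,
    consensus,
    region_weights,
    tau_scores,
)
from .inference import PermutationResult, permutation_test
from .io import StudyManifest, read_timeseries_tsv
from .preproc import (
    FD_THRESHOLD_MM,
    N_DISCARD_DEFAULT,
    bandpass,
    discard_initial,
    framewise_displacement,
    regress_nuisance,
    scrub,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "preprocess_series"]

DEFAULT_STAGE_ORDER = ("discard", "regress", "bandpass", "scrub")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the driver needs; every field is logged."""

    svm: SvmConfig = SvmConfig()
    n_discard: int = N_DISCARD_DEFAULT
    band: tuple = (0.01, 0.08)
    fd_threshold_mm: float = FD_THRESHOLD_MM
    stage_order: tuple = DEFAULT_STAGE_ORDER
    do_preproc: bool = True
    permutations: int = 1000
    perm_scheme: str = "free"
    seed: int = 0


@dataclass(frozen=True)
class PipelineReport:
    cv: CVResult
    consensus: ConsensusSet
    weights: np.ndarray
    permutation: PermutationResult | None
    region_ids: np.ndarray
    log: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "gr": self.cv.gr,
            "sensitivity": self.cv.sensitivity,
            "specificity": self.cv.specificity,
            "n_folds": self.cv.n_folds,
            "folds": [
                {
                    "sample_id": str(f.sample_id),
                    "y_true": f.y_true,
                    "y_pred": f.y_pred,
                    "decision_value": f.decision_value,
                    "n_selected": int(f.selected.size),
                }
                for f in self.cv.folds
            ],
            "consensus": {
                "edge_idx": self.consensus.edge_idx.tolist(),
                "sign": self.consensus.sign.tolist(),
                "n_edges": self.consensus.n_edges,
                "n_increased": self.consensus.n_increased,
                "n_decreased": self.consensus.n_decreased,
            },
            "region_weights": self.weights.tolist(),
            "region_ids": self.region_ids.tolist(),
            "log": self.log,
        }
        if self.permutation is not None:
            out["permutation"] = {
                "gr0": self.permutation.gr0,
                "p_value": self.permutation.p_value,
                "B": self.permutation.B,
                "scheme": self.permutation.scheme,
                "seed": self.permutation.seed,
                "n_redrawn": self.permutation.n_redrawn,
                "null_gr_mean": float(self.permutation.null_gr.mean()),
                "null_gr_q95": self.permutation.null_quantile(0.95),
                "null_histogram": _histogram(self.permutation.null_gr),
            }
        return out


def _histogram(values: np.ndarray, bins: int = 20) -> dict:
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return {"bin_edges": edges.tolist(), "counts": counts.tolist()}


def preprocess_series(ts, motion=None, config: PipelineConfig = PipelineConfig()):
    """Apply the configured preprocessing stages in the configured order.

    Returns the processed series and a per-stage log (frames discarded,
    frames interpolated). Scrubbing is skipped when no motion trace is
    supplied.
    """
    log = {"stage_order": list(config.stage_order), "n_interpolated": 0, "n_discarded": 0}
    fd = None
    for stage in config.stage_order:
        if stage == "discard":
            ts = discard_initial(ts, config.n_discard)
            log["n_discarded"] = config.n_discard
        elif stage == "regress":
            cov = None
            if motion is not None:
                p = motion.params
                if "discard" in config.stage_order and p.shape[0] == ts.n_frames + log["n_discarded"]:
                    p = p[log["n_discarded"] :]
                cov = p
            ts = regress_nuisance(ts, cov)
        elif stage == "bandpass":
            ts = bandpass(ts, *config.band)
        elif stage == "scrub":
            if motion is None:
                continue
            p = motion.params
            if p.shape[0] == ts.n_frames + log["n_discarded"]:
                from dataclasses import replace as _rep

                motion_t = _rep(motion, params=p[log["n_discarded"] :])
            else:
                motion_t = motion
            fd = framewise_displacement(motion_t, threshold_mm=config.fd_threshold_mm)
            ts, mask = scrub(ts, fd)
            log["n_interpolated"] = int(mask.sum())
        else:
            raise ValueError(f"unknown preprocessing stage {stage!r}")
    return ts, log


def manifest_to_labeled(
    manifest: StudyManifest, config: PipelineConfig = PipelineConfig(), root=None
) -> tuple[LabeledStudy, np.ndarray, dict]:
    """Load a manifest and produce the samples x features study.

    Time-series manifests are preprocessed (per config) and converted to
    Fisher-z connectivity vectors; feature-level manifests are loaded
    as-is. Mixing kinds is an error.
    """
    from .io import read_motion_txt

    root = Path(root) if root else Path(".")
    rows_feat, labels, subjects = [], [], []
    region_ids = None
    prep_log: dict = {}
    for r in manifest.rows:
        path = root / r.path
        if manifest.kind == "timeseries":
            ts = read_timeseries_tsv(path)
            motion = read_motion_txt(root / r.motion_path) if r.motion_path else None
            if config.do_preproc:
                ts, slog = preprocess_series(ts, motion, config)
                prep_log[f"{r.subject_id}/{r.session}"] = slog
            fv = vectorize_upper(correlation_matrix(ts))
            rows_feat.append(fv.z)
            ids = fv.region_ids
        elif manifest.kind == "features":
            import pandas as pd

            df = pd.read_csv(path, sep="\t", comment="#")
            vec = df.to_numpy(dtype=float).ravel()
            R = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
            if R * (R - 1) // 2 != vec.size:
                raise ValueError(
                    f"{path}: {vec.size} values is not R(R-1)/2 for any region count"
                )
            rows_feat.append(vec)
            ids = np.arange(1, R + 1)
        else:
            raise ValueError(f"manifest kind must be 'timeseries' or 'features', got {manifest.kind!r}")
        if region_ids is None:
            region_ids = ids
        elif not np.array_equal(region_ids, ids):
            raise ValueError(f"inconsistent region sets across manifest (at {r.path})")
        labels.append(r.label)
        subjects.append(r.subject_id)
    study = LabeledStudy(
        X=np.vstack(rows_feat), y=np.array(labels), subject_ids=np.array(subjects)
    )
    return study, region_ids, prep_log


def run_pipeline(
    study: LabeledStudy,
    config: PipelineConfig = PipelineConfig(),
    region_ids: np.ndarray | None = None,
    run_permutation: bool = True,
    extra_log: dict | None = None,
) -> PipelineReport:
    """LOOCV + consensus + region weights + permutation test on a study.

    ``region_ids`` defaults to 1..R with R recovered from the feature
    count (R(R-1)/2 features).
    """
    if region_ids is None:
        R = int(round((1 + np.sqrt(1 + 8 * study.n_features)) / 2))
        if R * (R - 1) // 2 != study.n_features:
            raise ValueError(
                f"{study.n_features} features is not R(R-1)/2 for any R; pass region_ids"
            )
        region_ids = np.arange(1, R + 1)
    R = len(region_ids)

    cache = PairSignCache(study.X)
    cv = loocv(study, config.svm, cache=cache)
    full_taus = tau_scores(study.X, study.y)
    cons = consensus(cv.selections, full_taus)
    weights = region_weights(cons, R)
    perm = None
    if run_permutation and config.permutations > 0:
        perm = permutation_test(
            study,
            config.svm,
            B=config.permutations,
            scheme=config.perm_scheme,
            seed=config.seed,
            cache=cache,
        )
    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": _config_dict(config),
        "n_samples": study.n_samples,
        "n_features": study.n_features,
        "n_regions": R,
    }
    if extra_log:
        log.update(extra_log)
    return PipelineReport(
        cv=cv,
        consensus=cons,
        weights=weights,
        permutation=perm,
        region_ids=np.asarray(region_ids),
        log=log,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["svm"] = asdict(config.svm)
    d["stage_order"] = list(config.stage_order)
    d["band"] = list(config.band)
    return d
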