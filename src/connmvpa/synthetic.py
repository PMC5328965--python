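"""Synthetic paired-design data with planted connectivity effects.

No data accompany the study this pipeline emulates, so every downstream
stage is verified against simulations with known ground truth. The
generator mirrors the study conditions: 25 subjects scanned in two
sessions (pre- and post-training), 175 retained frames at TR = 2 s, 116
brain regions, and a set of region-pair edges whose correlation shifts
between sessions by a known amount.

Per subject and session, frames are drawn i.i.d. from a zero-mean
multivariate Gaussian whose correlation matrix is a common base matrix
(constant off-diagonal ``base_corr``) plus the planted shifts on the
chosen edges (post session only) plus zero-mean subject-specific jitter,
repaired to the nearest valid correlation matrix by eigenvalue clipping.
The jitter keeps leave-one-out folds from being exchangeable copies of
one another without changing expected effects. Series are white by
default; an AR(1) coefficient adds temporal smoothness without altering
the zero-lag correlation structure (the AR filter is applied after the
spatial mixing, identically to every region). Optional white measurement
noise (``noise_sd``) attenuates all correlations by 1/(1+noise_sd^2).

Motion traces are a slow low-amplitude random walk on the six rigid-body
parameters with step-change spikes at chosen frames, for exercising the
frame-wise-displacement scrubbing path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import LabeledStudy
from .preproc import SPHERE_RADIUS_MM, MotionTrace, RoiTimeSeries

__all__ = [
    "PlantedEffect",
    "PairedStudy",
    "generate_paired_study",
    "generate_motion_trace",
    "generate_feature_dataset",
    "study_to_labeled",
]

JITTER_SD_DEFAULT = 0.02
EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class PlantedEffect:
    """Edges whose correlation shifts post-training, and by how much.

    ``edges`` are (i, j) region-ID pairs with 1 <= i < j; ``delta_r`` is
    the signed correlation shift per edge (scalar broadcasts); an optional
    ``direction`` (+1/-1 per edge) multiplies the shift.
    """

    edges: tuple = ()
    delta_r: tuple = ()
    direction: tuple = ()

    def __init__(self, edges=(), delta_r=0.3, direction=None):
        edges = tuple((int(i), int(j)) for i, j in edges)
        for i, j in edges:
            if not (1 <= i < j):
                raise ValueError(f"edge ({i},{j}) must satisfy 1 <= i < j")
        if len(set(edges)) != len(edges):
            raise ValueError("planted edges must be distinct")
        if np.isscalar(delta_r):
            deltas = (float(delta_r),) * len(edges)
        else:
            deltas = tuple(float(d) for d in delta_r)
            if len(deltas) != len(edges):
                raise ValueError("delta_r length must match edges")
        if direction is None:
            dirs = (1,) * len(edges)
        else:
            dirs = tuple(int(d) for d in direction)
            if len(dirs) != len(edges) or not all(d in (-1, 1) for d in dirs):
                raise ValueError("direction must be +-1 per edge")
        if any(abs(d) >= 1 for d in deltas):
            raise ValueError("|delta_r| must be < 1")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "delta_r", deltas)
        object.__setattr__(self, "direction", dirs)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def signed_deltas(self) -> np.ndarray:
        return np.array(self.delta_r) * np.array(self.direction)


@dataclass(frozen=True)
class PairedStudy:
    """One synthetic pre/post study: per-subject series plus the truth."""

    subjects: tuple
    pre: dict  # subject -> RoiTimeSeries
    post: dict
    truth: PlantedEffect
    seed: int
    jitter_sd: float = JITTER_SD_DEFAULT

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return self.pre[self.subjects[0]].n_regions


def _base_correlation(n_regions: int, base_corr: float) -> np.ndarray:
    C = np.full((n_regions, n_regions), base_corr)
    np.fill_diagonal(C, 1.0)
    return C


def _apply_effect(C: np.ndarray, effect: PlantedEffect) -> np.ndarray:
    C = C.copy()
    for (i, j), d in zip(effect.edges, effect.signed_deltas):
        if j > C.shape[0]:
            raise ValueError(f"planted edge ({i},{j}) outside the {C.shape[0]}-region atlas")
        target = C[i - 1, j - 1] + d
        if not -1 < target < 1:
            raise ValueError(
                f"planted edge ({i},{j}): target correlation {target:.3f} outside (-1, 1)"
            )
        C[i - 1, j - 1] = C[j - 1, i - 1] = target
    return C


def _nearest_valid_correlation(C: np.ndarray, context: str = "") -> np.ndarray:
    """Clip eigenvalues below a small floor and rescale to unit diagonal."""
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    w = np.clip(w, EIG_FLOOR, None)
    R = (V * w) @ V.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    if not np.all(np.linalg.eigvalsh(R) > 0):
        raise ValueError(f"could not repair correlation matrix to positive definite{context}")
    return R


def generate_paired_study(
    n_subjects: int = 25,
    n_regions: int = 116,
    n_frames: int = 175,
    tr: float = 2.0,
    base_corr: float = 0.1,
    effect: PlantedEffect = PlantedEffect(),
    noise_sd: float = 0.0,
    jitter_sd: float = JITTER_SD_DEFAULT,
    ar_coef: float = 0.0,
    seed: int = 0,
) -> PairedStudy:
    """Draw a paired pre/post study with the given planted effect.

    Defaults match the emulated study design: 25 subjects, 116 regions,
    175 frames at TR = 2 s. Bit-reproducible under ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_regions < 3:
        raise ValueError("need at least 3 regions")
    if not -1 < base_corr < 1:
        raise ValueError("base_corr must be in (-1, 1)")
    if not -1 < ar_coef < 1:
        raise ValueError("ar_coef must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    C_pre = _base_correlation(n_regions, base_corr)
    C_post = _apply_effect(C_pre, effect)
    region_ids = np.arange(1, n_regions + 1)
    subjects = tuple(f"sub{s + 1:03d}" for s in range(n_subjects))
    iu = np.triu_indices(n_regions, k=1)

    pre, post = {}, {}
    for subj in subjects:
        jitter = np.zeros((n_regions, n_regions))
        if jitter_sd > 0:
            vals = rng.normal(0.0, jitter_sd, size=iu[0].size)
            jitter[iu] = vals
            jitter = jitter + jitter.T
        for session, C, store in (("pre", C_pre, pre), ("post", C_post, post)):
            Cs = _nearest_valid_correlation(
                np.clip(C + jitter, -0.999, 0.999), context=f" (subject {subj}, {session})"
            )
            L = np.linalg.cholesky(Cs)
            x = rng.standard_normal((n_frames, n_regions)) @ L.T
            if ar_coef != 0.0:
                for t in range(1, n_frames):
                    x[t] += ar_coef * x[t - 1]
                x *= np.sqrt(1.0 - ar_coef**2)  # restore unit variance
            if noise_sd > 0:
                x = x + rng.normal(0.0, noise_sd, size=x.shape)
            store[subj] = RoiTimeSeries(data=x, tr=tr, region_ids=region_ids)
    return PairedStudy(
        subjects=subjects, pre=pre, post=post, truth=effect, seed=seed, jitter_sd=jitter_sd
    )


def generate_motion_trace(
    n_frames: int = 175,
    spike_frames: tuple = (),
    spike_translation_mm: float = 1.0,
    spike_rotation: float = 0.0,
    baseline_sd: float = 0.01,
    seed: int = 0,
) -> MotionTrace:
    """Six-parameter motion trace: slow random walk plus step spikes.

    A spike at frame k (1-based, k >= 2) is a step change of
    ``spike_translation_mm`` on the x-translation and ``spike_rotation``
    (radians) on the x-rotation, persisting from frame k on -- so the
    frame-wise displacement spikes exactly at frame k. Frame 1 cannot
    host a spike (FD is defined as 0 there).

    ``baseline_sd`` is the per-frame step SD of the walk in mm; rotation
    steps use baseline_sd/50 radians so that, after the 50 mm arc-length
    conversion, each of the six parameters contributes comparably to FD
    (a quiet subject at the default 0.01 mm sits well under the 0.5 mm
    scrubbing threshold).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    for f in spike_frames:
        if not 2 <= f <= n_frames:
            raise ValueError(f"spike frame {f} outside [2, {n_frames}] (FD undefined at frame 1)")
    rng = np.random.default_rng(seed)
    if baseline_sd > 0:
        sds = np.array([baseline_sd] * 3 + [baseline_sd / SPHERE_RADIUS_MM] * 3)
        steps = rng.normal(0.0, 1.0, size=(n_frames, 6)) * sds
    else:
        steps = np.zeros((n_frames, 6))
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    for f in spike_frames:
        params[f - 1 :, 0] += spike_translation_mm
        params[f - 1 :, 3] += spike_rotation
    return MotionTrace(params=params, unit="rad")


def generate_feature_dataset(
    n_per_class: int = 25,
    n_features: int = 50,
    informative_idx: tuple = (),
    effect_size: float = 0.0,
    seed: int = 0,
) -> LabeledStudy:
    """Feature-level shortcut: Gaussian features, a between-class mean
    shift of ``effect_size`` on the informative ones, balanced +-1 labels,
    paired subject IDs. Used for classifier and permutation unit tests
    without the time-series stage."""
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    informative = np.asarray(informative_idx, dtype=int)
    if informative.size and not (
        informative.min() >= 1 and informative.max() <= n_features
    ):
        raise ValueError("informative_idx must lie in [1, n_features]")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    y = np.concatenate([np.ones(n_per_class, dtype=int), -np.ones(n_per_class, dtype=int)])
    if informative.size:
        X[: n_per_class, informative - 1] += effect_size
    subjects = np.array([f"sub{s + 1:03d}" for s in range(n_per_class)] * 2)
    return LabeledStudy(X=X, y=y, subject_ids=subjects)


def study_to_labeled(study: PairedStudy) -> LabeledStudy:
    """Connectivity features for every subject/session of a paired study.

    Runs correlation + Fisher-z vectorization per series and stacks the
    results into a LabeledStudy (+1 = post, -1 = pre).
    """
    from .connectivity import correlation_matrix, vectorize_upper

    rows, labels, subj = [], [], []
    for session, store, lab in (("pre", study.pre, -1), ("post", study.post, 1)):
        for s in study.subjects:
            rows.append(vectorize_upper(correlation_matrix(store[s])).z)
            labels.append(lab)
            subj.append(s)
    return LabeledStudy(X=np.vstack(rows), y=np.array(labels), subject_ids=np.array(subj))
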