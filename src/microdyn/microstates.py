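"""Microstate segmentation and dynamics features.

Pipeline: global field power (GFP) -> topographies at GFP peaks ->
polarity-invariant ("modified") k-means with GEV-maximising restarts ->
two-level (individual, then group) clustering -> canonical A-D labelling
against reference gradients -> per-sample back-fitting -> dynamics
features (mean duration, occurrence, coverage, transition probabilities;
4+4+4+12 = 24 features at K = 4).

Scalp maps are sign-ambiguous at rest, so every spatial comparison here is
polarity invariant by default: assignment uses |Pearson correlation| and
cluster centroids are dominant eigenvectors of the assigned maps' channel
covariance rather than arithmetic means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .recording import Recording
from .synthetic import (
    LabelSequence,
    STATE_NAMES,
    TopographyTemplate,
    make_templates,
)

__all__ = [
    "GfpSeries",
    "MicrostateModel",
    "MicrostateFeatures",
    "compute_gfp",
    "find_gfp_peaks",
    "spatial_correlation",
    "cluster_microstates",
    "compute_gev",
    "group_level_model",
    "reorient_to_abcd",
    "backfit",
    "extract_features",
    "features_to_frame",
    "FEATURE_COLUMNS",
]


@dataclass(frozen=True)
class GfpSeries:
    """Per-sample spatial standard deviation of the scalp field (µV)."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("GFP values must be nonnegative")
        object.__setattr__(self, "values", v)


@dataclass
class MicrostateModel:
    """K unit-norm, average-referenced topographies plus fit bookkeeping."""

    maps: np.ndarray                      # (K, n_channels)
    gev: float
    k: int
    n_restarts: int = 1
    seed: int = 0
    labels: list[str] | None = None       # canonical A-D labels, once assigned

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] != self.k:
            raise ValueError("maps must be (K, n_channels)")
        if not 0.0 <= self.gev <= 1.0 + 1e-12:
            raise ValueError(f"GEV must lie in [0, 1], got {self.gev}")

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def map_by_label(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("model has no canonical labels yet")
        return self.maps[self.labels.index(label)]


@dataclass(frozen=True)
class MicrostateFeatures:
    """Dynamics features of one label sequence (per state, K states)."""

    duration_ms: np.ndarray
    occurrence_hz: np.ndarray
    coverage_frac: np.ndarray
    transitions: np.ndarray               # (K, K), zero diagonal

    def flatten(self) -> np.ndarray:
        k = self.duration_ms.size
        off = ~np.eye(k, dtype=bool)
        return np.concatenate(
            [
                self.duration_ms,
                self.occurrence_hz,
                self.coverage_frac,
                self.transitions[off],
            ]
        )


def _feature_columns(k: int = 4) -> list[str]:
    names = list(STATE_NAMES[:k])
    cols = [f"dur_{s}" for s in names]
    cols += [f"occ_{s}" for s in names]
    cols += [f"cov_{s}" for s in names]
    cols += [
        f"tp_{a}_{b}" for a in names for b in names if a != b
    ]
    return cols


FEATURE_COLUMNS = _feature_columns(4)


# ---------------------------------------------------------------------------
# GFP and peaks
# ---------------------------------------------------------------------------

def compute_gfp(rec: Recording) -> GfpSeries:
    """GFP(t) = sqrt(mean_i (V_i(t) - Vbar(t))^2): the spatial SD per sample."""
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least two channels")
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    return GfpSeries(values=np.sqrt(np.mean(centered ** 2, axis=0)), fs=rec.fs)


def find_gfp_peaks(gfp: GfpSeries) -> np.ndarray:
    """Interior local maxima of the GFP curve.

    A sample t is a peak when gfp[t-1] < gfp[t] >= gfp[t+1]; a flat plateau
    therefore contributes its first sample.  Endpoints are never peaks.
    """
    v = gfp.values
    if v.size < 3:
        raise ValueError("need at least 3 samples to find peaks")
    rising = v[1:-1] > v[:-2]
    not_falling_yet = v[1:-1] >= v[2:]
    return np.flatnonzero(rising & not_falling_yet) + 1


def spatial_correlation(
    u: np.ndarray, v: np.ndarray, polarity_invariant: bool = True
) -> float:
    """Pearson correlation of two scalp maps across channels."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("maps must have equal channel counts")
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise ValueError("zero-variance map has no spatial correlation")
    r = float(np.dot(uc, vc) / (nu * nv))
    return abs(r) if polarity_invariant else r


# ---------------------------------------------------------------------------
# modified k-means
# ---------------------------------------------------------------------------

def _center_normalize(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-reference each map and scale rows to unit norm.

    Returns the normalized rows plus the original row norms (the map
    'strength', proportional to GFP)."""
    centered = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return centered / safe[:, None], norms


def _dominant_eigenvector(x: np.ndarray, prev: np.ndarray) -> np.ndarray:
    """Leading eigenvector of x.T @ x, sign-aligned with ``prev``."""
    cov = x.T @ x
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    if np.dot(v, prev) < 0:
        v = -v
    return v


def _peak_gev(
    corr_abs: np.ndarray, assign: np.ndarray, weights: np.ndarray
) -> float:
    """GFP^2-weighted mean squared assigned correlation over the peak maps."""
    num = float(np.sum(weights * corr_abs[np.arange(assign.size), assign] ** 2))
    den = float(np.sum(weights))
    return num / den if den > 0 else 0.0


def cluster_microstates(
    peak_maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 100,
    seed: int = 0,
    max_iter: int = 100,
    polarity_invariant: bool = True,
) -> MicrostateModel:
    """Modified k-means over topographies with best-of-``n_restarts`` by GEV.

    Assignment maximizes the squared spatial correlation to the current
    maps; the centroid update replaces each map by the dominant eigenvector
    of its assigned maps' channel covariance (the polarity-blind least-
    squares topography).  With ``polarity_invariant=False`` plain k-means
    behaviour is obtained: signed correlation and arithmetic-mean centroids.
    """
    peak_maps = np.asarray(peak_maps, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    x, strengths = _center_normalize(peak_maps)
    keep = strengths > 0
    x, strengths = x[keep], strengths[keep]
    if np.unique(np.round(x, 12), axis=0).shape[0] < k:
        raise ValueError("fewer than k distinct peak topographies")
    weights = strengths ** 2

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    n = x.shape[0]
    for _ in range(max(1, n_restarts)):
        maps = x[rng.choice(n, size=k, replace=False)].copy()
        assign = np.full(n, -1)
        for _ in range(max_iter):
            corr = x @ maps.T
            signed = np.abs(corr) if polarity_invariant else corr
            new_assign = np.argmax(signed, axis=1)
            # re-seed empty clusters from the worst-fitting map
            for kk in range(k):
                if not np.any(new_assign == kk):
                    worst = np.argmin(signed.max(axis=1))
                    new_assign[worst] = kk
                    maps[kk] = x[worst]
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for kk in range(k):
                members = x[assign == kk]
                if polarity_invariant:
                    maps[kk] = _dominant_eigenvector(members, maps[kk])
                else:
                    m = members.mean(axis=0)
                    nm = np.linalg.norm(m)
                    maps[kk] = m / nm if nm > 0 else maps[kk]
        corr = x @ maps.T
        signed = np.abs(corr) if polarity_invariant else corr
        gev = _peak_gev(np.abs(corr), np.argmax(signed, axis=1), weights)
        if best is None or gev > best[0]:
            best = (gev, maps.copy())

    gev, maps = best
    maps, _ = _center_normalize(maps)
    return MicrostateModel(
        maps=maps, gev=float(gev), k=k, n_restarts=n_restarts, seed=seed
    )


def compute_gev(
    model: MicrostateModel, rec: Recording, labels: LabelSequence
) -> float:
    """Global explained variance of the data under an assignment.

    GEV = sum_t GFP(t)^2 corr^2(V(t), map_{L(t)}) / sum_t GFP(t)^2 with
    polarity-invariant correlation; zero-field samples contribute nothing
    to the numerator.
    """
    if labels.labels.size != rec.n_samples:
        raise ValueError("label sequence length does not match recording")
    x, strengths = _center_normalize(rec.data.T)
    if not np.any(strengths > 0):
        raise ValueError("all-zero recording has undefined GEV")
    maps, _ = _center_normalize(model.maps)
    corr = np.abs(np.einsum("tc,tc->t", x, maps[labels.labels]))
    w = strengths ** 2
    return float(np.sum(w * corr ** 2) / np.sum(w))


# ---------------------------------------------------------------------------
# two-level clustering and canonical labels
# ---------------------------------------------------------------------------

def group_level_model(
    individual_models: list[MicrostateModel],
    k: int = 4,
    n_restarts: int = 100,
    seed: int = 0,
) -> MicrostateModel:
    """Pool all subjects' individual maps and re-cluster them."""
    if not individual_models:
        raise ValueError("no individual models to pool")
    n_ch = individual_models[0].n_channels
    if any(m.n_channels != n_ch for m in individual_models):
        raise ValueError("individual models disagree on channel count")
    pooled = np.vstack([m.maps for m in individual_models])
    return cluster_microstates(pooled, k=k, n_restarts=n_restarts, seed=seed)


def _best_permutation(
    maps: np.ndarray, refs: np.ndarray
) -> tuple[tuple[int, ...], float]:
    """Exhaustive map-to-reference matching by summed |spatial correlation|.

    Returns the permutation p (maps[p[j]] matches refs[j]) and its score.
    """
    k = refs.shape[0]
    corr = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = spatial_correlation(maps[i], refs[j])
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(corr[perm[j], j] for j in range(k))
        if score > best_score:
            best_perm, best_score = perm, score
    return best_perm, float(best_score)


def mean_model(models: list[MicrostateModel]) -> MicrostateModel:
    """Average several K-map models after aligning order and polarity."""
    ref = models[0].maps
    acc = np.zeros_like(ref)
    for m in models:
        perm, _ = _best_permutation(m.maps, ref)
        for j in range(ref.shape[0]):
            v = m.maps[perm[j]]
            if np.dot(v, ref[j]) < 0:
                v = -v
            acc[j] += v
    maps, _ = _center_normalize(acc)
    return MicrostateModel(
        maps=maps, gev=0.0, k=ref.shape[0], n_restarts=0, seed=models[0].seed
    )


def reorient_to_abcd(
    models: list[MicrostateModel],
    reference_templates: list[TopographyTemplate] | None = None,
) -> tuple[list[MicrostateModel], MicrostateModel]:
    """Assign canonical A-D labels to a set of group models.

    The cross-group mean model is matched to the four reference gradients
    by the exhaustive best permutation over summed |spatial correlation|;
    each group model is then matched to the labelled mean maps the same
    way.  Returns the relabelled (map-reordered) group models and the
    labelled mean model.
    """
    if not models:
        raise ValueError("no models to reorient")
    if any(m.k != 4 for m in models):
        raise ValueError("canonical A-D labelling requires K = 4")
    if reference_templates is None:
        reference_templates = make_templates(models[0].n_channels, seed=0)
    refs = np.stack([t.values for t in reference_templates])
    if refs.shape != (4, models[0].n_channels):
        raise ValueError("need four reference templates with matching channels")

    mean = mean_model(models)
    perm, _ = _best_permutation(mean.maps, refs)
    mean_labeled = replace(mean)
    mean_labeled.maps = mean.maps[list(perm)]
    mean_labeled.labels = list(STATE_NAMES)

    out = []
    for m in models:
        p, _ = _best_permutation(m.maps, mean_labeled.maps)
        relabeled = replace(m)
        relabeled.maps = m.maps[list(p)]
        relabeled.labels = list(STATE_NAMES)
        out.append(relabeled)
    return out, mean_labeled


# ---------------------------------------------------------------------------
# back-fitting and features
# ---------------------------------------------------------------------------

def backfit(
    rec: Recording,
    model: MicrostateModel,
    polarity_invariant: bool = True,
    evidence_half_width: int = 0,
    neighbor_weight: float = 0.5,
    restrict_to_peaks: bool = False,
) -> LabelSequence:
    """Label every sample with the best-correlated microstate map.

    With the default ``evidence_half_width=0`` this is the plain per-sample
    rule: argmax over maps of the (absolute) spatial correlation; ties keep
    the previous sample's label (first sample: lowest index) and
    zero-variance samples inherit the previous label, or index 0 at the
    start.  No temporal smoothing is applied.

    With ``evidence_half_width=w > 0`` the per-sample assignment evidence
    ``GFP(t)^2 * corr^2(V(t), map_k)`` is aggregated over a triangular
    window of ±w samples (neighbours down-weighted by
    ``neighbor_weight**distance``) before the argmax.  Samples where the
    field passes through zero carry almost no evidence of their own, so
    their labels are otherwise decided by noise; borrowing the neighbouring
    samples' evidence removes those spurious one-sample state flips without
    suppressing genuine short microstate segments.

    ``restrict_to_peaks=True`` is the alternative convention that labels
    only the GFP peaks and assigns every other sample the label of its
    nearest peak.
    """
    if rec.n_channels != model.n_channels:
        raise ValueError("recording and model channel counts differ")
    x, strengths = _center_normalize(rec.data.T)
    maps, _ = _center_normalize(model.maps)
    corr = x @ maps.T
    score = np.abs(corr) if polarity_invariant else corr

    if restrict_to_peaks:
        gfp = GfpSeries(values=strengths / np.sqrt(x.shape[1]), fs=rec.fs)
        peaks = find_gfp_peaks(gfp)
        if peaks.size == 0:
            raise ValueError("no GFP peaks to back-fit")
        peak_labels = np.argmax(score[peaks], axis=1)
        nearest = np.searchsorted(peaks, np.arange(x.shape[0]))
        nearest = np.clip(nearest, 0, peaks.size - 1)
        left = np.clip(nearest - 1, 0, peaks.size - 1)
        use_left = np.abs(peaks[left] - np.arange(x.shape[0])) <= np.abs(
            peaks[nearest] - np.arange(x.shape[0])
        )
        idx = np.where(use_left, left, nearest)
        return LabelSequence(
            labels=peak_labels[idx], fs=rec.fs, n_states=model.k
        )

    if evidence_half_width > 0:
        # GFP^2-weighted squared correlation, pooled over the window
        evidence = (corr * strengths[:, None]) ** 2
        offsets = np.arange(-evidence_half_width, evidence_half_width + 1)
        kernel = neighbor_weight ** np.abs(offsets).astype(float)
        pooled = np.stack(
            [
                np.convolve(evidence[:, k], kernel, mode="same")
                for k in range(model.k)
            ],
            axis=1,
        )
        labels = np.argmax(pooled, axis=1)
        return LabelSequence(labels=labels, fs=rec.fs, n_states=model.k)

    labels = np.argmax(score, axis=1)
    top = score[np.arange(score.shape[0]), labels]
    n_top = np.sum(np.isclose(score, top[:, None], rtol=0.0, atol=1e-12), axis=1)
    degenerate = np.flatnonzero((n_top > 1) | (strengths <= 0))
    for t in degenerate:
        labels[t] = labels[t - 1] if t > 0 else 0
    return LabelSequence(labels=labels, fs=rec.fs, n_states=model.k)


def extract_features(seq: LabelSequence) -> MicrostateFeatures:
    """Run-length statistics of a label sequence.

    Boundary (truncated first/last) segments are included.  Transition
    probabilities are per-source-state over consecutive distinct segments:
    row i is the empirical distribution of the state following a state-i
    segment, which makes the 12 off-diagonal entries independent of
    recording length.  States that never occur get zero duration,
    occurrence, coverage and a zero transition row.
    """
    lab = seq.labels
    k = seq.n_states
    total_s = lab.size / seq.fs

    starts = np.concatenate([[0], np.flatnonzero(np.diff(lab) != 0) + 1])
    lengths = np.diff(np.concatenate([starts, [lab.size]]))
    seg_states = lab[starts]

    duration = np.zeros(k)
    occurrence = np.zeros(k)
    coverage = np.zeros(k)
    for s in range(k):
        mine = seg_states == s
        if mine.any():
            duration[s] = lengths[mine].mean() * 1000.0 / seq.fs
            occurrence[s] = mine.sum() / total_s
            coverage[s] = lengths[mine].sum() / lab.size

    transitions = np.zeros((k, k))
    np.add.at(transitions, (seg_states[:-1], seg_states[1:]), 1.0)
    np.fill_diagonal(transitions, 0.0)
    rowsum = transitions.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        transitions = np.where(rowsum > 0, transitions / rowsum, 0.0)

    return MicrostateFeatures(
        duration_ms=duration,
        occurrence_hz=occurrence,
        coverage_frac=coverage,
        transitions=transitions,
    )


def features_to_frame(
    features: list[MicrostateFeatures], subject_ids: list[str]
) -> pd.DataFrame:
    """One row per subject, 24 named columns (dur/occ/cov/tp), id-indexed."""
    if len(features) != len(subject_ids):
        raise ValueError("one feature set per subject id required")
    k = features[0].duration_ms.size
    rows = np.stack([f.flatten() for f in features])
    frame = pd.DataFrame(rows, columns=_feature_columns(k))
    frame.insert(0, "subject_id", subject_ids)
    return frame.set_index("subject_id")
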