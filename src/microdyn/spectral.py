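"""Band power, theta/beta ratio, subject x channel power matrices, and
group ICA over those matrices.

Absolute band power per channel is the Welch PSD (2-s Hamming windows,
50% overlap) integrated over the band with the trapezoid rule on the FFT
grid, in µV².  Per band the cohort forms an (n_subjects x n_channels)
matrix; ICA decomposes it as ``X ≈ A S`` with spatial maps ``S`` (rows,
independent across channels) and per-subject loadings ``A`` (columns),
using PCA reduction followed by extended Infomax unmixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sst

from .recording import Recording

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "PowerMatrix",
    "IcaResult",
    "band_power",
    "theta_beta_ratio",
    "build_power_matrices",
    "ica_decompose",
    "ica_sweep",
    "orient_and_zscore",
    "test_components",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band {self.name}: ({self.low}, {self.high})")


DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("low_alpha", 8.0, 10.0),
    BandDefinition("high_alpha", 10.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)


@dataclass
class PowerMatrix:
    """Subjects x channels absolute power (µV²) or ratio for one band."""

    values: pd.DataFrame  # index: subject ids, columns: channel names
    band: str

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class IcaResult:
    """Group ICA of one power matrix.

    ``loadings @ spatial_maps`` reconstructs the rank-M approximation of
    the column-centred matrix; ``zmaps`` are the spatial maps standardized
    across channels per component.
    """

    band: str
    loadings: pd.DataFrame       # subjects x M
    spatial_maps: pd.DataFrame   # M x channels
    zmaps: pd.DataFrame          # M x channels, per-row mean 0 / SD 1
    n_components: int
    seed: int
    orientation: np.ndarray = field(default_factory=lambda: np.array([]))


def band_power(rec: Recording, band: BandDefinition) -> np.ndarray:
    """Absolute power per channel over [band.low, band.high], µV²."""
    if band.high >= rec.fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.high} Hz is not below "
            f"Nyquist ({rec.fs / 2} Hz)"
        )
    nperseg = int(round(2.0 * rec.fs))
    if rec.n_samples < nperseg:
        raise ValueError("recording shorter than one 2-s Welch window")
    freqs, psd = sps.welch(
        rec.data,
        fs=rec.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        axis=1,
    )
    mask = (freqs >= band.low) & (freqs <= band.high)
    return np.trapezoid(psd[:, mask], freqs[mask], axis=1)


def theta_beta_ratio(theta: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Element-wise theta/beta power ratio per channel."""
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    bad = np.flatnonzero(beta <= 0)
    if bad.size:
        raise ValueError(f"zero beta power in channel index(es) {bad.tolist()}")
    return theta / beta


def build_power_matrices(
    recordings: list[Recording],
    subject_ids: list[str],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    include_tbr: bool = True,
) -> dict[str, PowerMatrix]:
    """One subjects x channels matrix per band, plus the TBR matrix."""
    if len(recordings) != len(subject_ids):
        raise ValueError("one subject id per recording required")
    names = recordings[0].channel_names
    fs = recordings[0].fs
    for rec in recordings:
        if rec.channel_names != names or rec.fs != fs:
            raise ValueError("recordings disagree on channels or sampling rate")
    per_band = {
        band.name: np.stack([band_power(rec, band) for rec in recordings])
        for band in bands
    }
    out = {
        name: PowerMatrix(
            values=pd.DataFrame(vals, index=list(subject_ids), columns=names),
            band=name,
        )
        for name, vals in per_band.items()
    }
    if include_tbr:
        if "theta" not in per_band or "beta" not in per_band:
            raise ValueError("TBR requires theta and beta bands")
        tbr = np.stack(
            [
                theta_beta_ratio(per_band["theta"][i], per_band["beta"][i])
                for i in range(len(recordings))
            ]
        )
        out["tbr"] = PowerMatrix(
            values=pd.DataFrame(tbr, index=list(subject_ids), columns=names),
            band="tbr",
        )
    return out


def ica_decompose(
    pm: PowerMatrix,
    n_components: int,
    seed: int = 0,
    max_iter: int = 2000,
) -> IcaResult:
    """PCA-reduced extended-Infomax ICA of a power matrix.

    The matrix is column-centred (per channel, across subjects), reduced to
    ``n_components`` principal directions over subjects, and the component
    "time courses" over channels are unmixed by extended Infomax.  Spatial
    maps are the independent rows over channels; loadings are the
    least-squares per-subject coefficients.
    """
    x = pm.values.to_numpy(dtype=float)
    n_subj, n_ch = x.shape
    if not 1 <= n_components <= min(n_subj, n_ch):
        raise ValueError(
            f"n_components={n_components} must be in [1, {min(n_subj, n_ch)}]"
        )
    from mne.preprocessing import infomax

    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # principal component scores over channels, whitened row-wise
    pcs = vt[:n_components] * s[:n_components, None]
    row_sd = pcs.std(axis=1, keepdims=True)
    pcs_w = pcs / row_sd
    unmixing = infomax(
        pcs_w.T,
        extended=True,
        max_iter=max_iter,
        rng=np.random.default_rng(seed),
        verbose="error",
    )
    sources = unmixing @ pcs_w  # (M, n_channels)
    # fix component scale/sign convention: unit variance across channels
    sources /= sources.std(axis=1, keepdims=True)
    loadings, *_ = np.linalg.lstsq(sources.T, xc.T, rcond=None)
    loadings = loadings.T  # (n_subjects, M)

    comp_names = [f"IC{i + 1}" for i in range(n_components)]
    zmaps = (sources - sources.mean(axis=1, keepdims=True)) / sources.std(
        axis=1, keepdims=True
    )
    return IcaResult(
        band=pm.band,
        loadings=pd.DataFrame(loadings, index=pm.values.index, columns=comp_names),
        spatial_maps=pd.DataFrame(
            sources, index=comp_names, columns=pm.values.columns
        ),
        zmaps=pd.DataFrame(zmaps, index=comp_names, columns=pm.values.columns),
        n_components=n_components,
        seed=seed,
        orientation=np.ones(n_components),
    )


def ica_sweep(
    pm: PowerMatrix, components: range = range(5, 11), seed: int = 0
) -> dict[int, IcaResult]:
    """Decompose one power matrix at every model order in ``components``."""
    return {m: ica_decompose(pm, m, seed=seed) for m in components}


def orient_and_zscore(
    result: IcaResult, group_labels: pd.Series, reference_group: str
) -> IcaResult:
    """Flip component signs so the reference group's mean loading is higher.

    Loadings and spatial maps flip jointly, so the model product is
    unchanged; applying the orientation twice is a no-op.
    """
    groups = pd.Series(group_labels).reindex(result.loadings.index)
    levels = groups.unique()
    if len(levels) != 2 or reference_group not in levels:
        raise ValueError("orientation needs exactly two groups incl. the reference")
    ref = groups == reference_group
    flips = np.where(
        result.loadings[ref].mean(axis=0).to_numpy()
        >= result.loadings[~ref].mean(axis=0).to_numpy(),
        1.0,
        -1.0,
    )
    loadings = result.loadings * flips
    maps = result.spatial_maps.mul(flips, axis=0)
    zmaps = (maps.sub(maps.mean(axis=1), axis=0)).div(
        maps.std(axis=1, ddof=0), axis=0
    )
    return IcaResult(
        band=result.band,
        loadings=loadings,
        spatial_maps=maps,
        zmaps=zmaps,
        n_components=result.n_components,
        seed=result.seed,
        orientation=flips * result.orientation,
    )


def test_components(
    result: IcaResult,
    group_labels: pd.Series,
    alpha: float = 0.05,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-component two-sample t-test on loadings, Bonferroni over M.

    Returns one row per component with the t statistic, p value, the
    Bonferroni-corrected significance flag (p < alpha / M), and the
    |Z| > ``z_threshold`` channel set for significant components.
    """
    groups = pd.Series(group_labels).reindex(result.loadings.index)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("component testing requires exactly two groups")
    a = result.loadings[groups == levels[0]]
    b = result.loadings[groups == levels[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least two subjects per group")
    m = result.n_components
    rows = []
    for comp in result.loadings.columns:
        x, y = a[comp].to_numpy(), b[comp].to_numpy()
        if np.var(x) + np.var(y) == 0:
            raise ValueError(f"degenerate (zero-variance) loadings for {comp}")
        t, p = sst.ttest_ind(x, y, equal_var=True)
        significant = bool(p < alpha / m)
        zrow = result.zmaps.loc[comp]
        selected = (
            list(zrow.index[np.abs(zrow.to_numpy()) > z_threshold])
            if significant
            else []
        )
        rows.append(
            {
                "component": comp,
                "t": float(t),
                "p": float(p),
                "alpha": alpha,
                "n_comparisons": m,
                "significant": significant,
                "selected_channels": selected,
            }
        )
    return pd.DataFrame(rows).set_index("component")
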