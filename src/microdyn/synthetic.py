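"""Synthetic resting-state EEG cohorts with known microstate dynamics.

The generator emulates eyes-closed, average-referenced, high-density EEG as
a four-state quasi-stable microstate process: a first-order Markov chain
with geometric dwell times selects which of four fixed scalp topographies
is active; the active map rides on a waxing-and-waning oscillatory
alpha/theta carrier with a random polarity per microstate segment,
band-limited sinusoidal oscillations are added inside scalp regions, and
white sensor noise on every channel.  Two clinical groups (and two patient subtypes)
differ in their planted transition structure, dwell times and regional
band-power amplitudes, and the planted parameters are returned alongside
the data so downstream stages can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import Recording

STATE_NAMES = ("A", "B", "C", "D")

#: representative carrier frequency (Hz) used when planting a band effect
BAND_CENTER_HZ = {
    "delta": 2.5,
    "theta": 6.0,
    "low_alpha": 9.0,
    "high_alpha": 11.0,
    "beta": 20.0,
    "gamma": 40.0,
}


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def disc_positions(n_channels: int) -> np.ndarray:
    """Deterministic sunflower layout of ``n_channels`` points on the unit
    disc; x grows to the right, y to the front (anterior)."""
    if n_channels < 8:
        raise ValueError("need at least 8 channels to lay out a montage")
    i = np.arange(n_channels, dtype=float)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt((i + 0.5) / n_channels)
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def channel_names(n_channels: int) -> list[str]:
    return [f"SYN{i + 1:03d}" for i in range(n_channels)]


def region_mask(region: str, positions: np.ndarray) -> np.ndarray:
    """Boolean channel mask for a named scalp region on the disc montage."""
    x, y = positions[:, 0], positions[:, 1]
    if region == "fronto-central":
        return (x ** 2 + (y - 0.45) ** 2) < 0.35 ** 2
    if region == "fronto-temporal":
        return (y > 0.0) & (np.abs(x) > 0.55)
    if region == "posterior-occipital":
        return y < -0.55
    raise ValueError(f"unknown region {region!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopographyTemplate:
    """A unit-norm, average-referenced scalp map with a canonical label."""

    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if abs(v.mean()) > 1e-9:
            raise ValueError("template must be average-referenced (mean 0)")
        if abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise ValueError("template must have unit vector norm")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MarkovSpec:
    """Dwell/transition model of the microstate sequence.

    ``mean_durations_ms`` sets the geometric dwell mean per state;
    ``transition_matrix`` is row-stochastic with zero diagonal and governs
    which state follows when a segment ends.
    """

    mean_durations_ms: np.ndarray
    transition_matrix: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        dur = np.asarray(self.mean_durations_ms, dtype=float)
        tm = np.asarray(self.transition_matrix, dtype=float)
        if (dur <= 0).any():
            raise ValueError("mean durations must be positive")
        if tm.shape != (dur.size, dur.size):
            raise ValueError("transition matrix shape inconsistent with durations")
        if np.abs(np.diag(tm)).max() != 0.0:
            raise ValueError("transition matrix diagonal must be exactly zero")
        if (tm < 0).any() or np.abs(tm.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition matrix rows must sum to 1")
        object.__setattr__(self, "mean_durations_ms", dur)
        object.__setattr__(self, "transition_matrix", tm)

    @property
    def n_states(self) -> int:
        return self.mean_durations_ms.size

    def stationary_coverage(self) -> np.ndarray:
        """Long-run fraction of *time* in each state: the segment-chain
        stationary distribution weighted by mean dwell."""
        tm = self.transition_matrix
        vals, vecs = np.linalg.eig(tm.T)
        pi = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
        pi = np.abs(pi) / np.abs(pi).sum()
        w = pi * self.mean_durations_ms
        return w / w.sum()


@dataclass(frozen=True)
class LabelSequence:
    """Per-sample microstate assignment (state indices 0..K-1)."""

    labels: np.ndarray
    fs: float
    n_states: int = 4

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.ndim != 1 or lab.size == 0:
            raise ValueError("labels must be a nonempty 1-D array")
        if lab.min() < 0 or lab.max() >= self.n_states:
            raise ValueError("label out of range")
        object.__setattr__(self, "labels", lab)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs for a synthetic two-group / two-subtype cohort.

    Defaults reproduce the reference cohort: 54 controls, 107 patients
    (53 combined-subtype, 54 inattentive), 91 channels at 250 Hz, 120 s per
    subject.  The planted effects mirror the directions reported for this
    design: patients have weaker A<->C switching and state-C inflow, stronger
    B<->D switching and longer state-D dwell, plus extra fronto-central delta
    and fronto-temporal theta (hence theta/beta ratio); the combined subtype
    additionally shows shorter state-A dwell, more state-B inflow and extra
    posterior-occipital gamma.
    """

    n_hc: int = 54
    n_adhd_c: int = 53
    n_adhd_i: int = 54
    n_channels: int = 91
    fs: float = 250.0
    duration_s: float = 120.0
    noise_sd: float = 1.0          # µV per channel, white
    amplitude_uv: float = 40.0     # microstate signal coefficient
    transition_ms: float = 20.0    # crossfade width at segment boundaries
    mean_duration_ms: float = 80.0
    adhd_d_duration_ms: float = 95.0
    adhd_c_a_duration_ms: float = 70.0
    trans_delta: float = 0.10      # A<->C down / B<->D up in patients
    c_inflow_scale: float = 0.20   # fractional reduction of ->C inflow
    subtype_trans_delta: float = 0.08
    b_inflow_scale: float = 0.15   # fractional boost of ->B inflow in ADHD-C
    delta_base_uv: float = 1.0
    delta_shift_uv: float = 1.5    # extra fronto-central delta in patients
    theta_base_uv: float = 1.0
    theta_shift_uv: float = 1.2    # extra fronto-temporal theta in patients
    gamma_base_uv: float = 0.8
    gamma_shift_uv: float = 1.2    # extra posterior-occipital gamma in ADHD-C
    subject_amp_sd: float = 0.3    # between-subject SD of band amplitudes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 8:
            raise ValueError("n_channels must be at least 8")
        if self.fs <= 90.0:
            raise ValueError("fs must exceed twice the 45 Hz band edge")
        if min(self.n_hc, self.n_adhd_c, self.n_adhd_i) < 1:
            raise ValueError("each group needs at least one subject")

    @property
    def n_subjects(self) -> int:
        return self.n_hc + self.n_adhd_c + self.n_adhd_i


@dataclass
class Cohort:
    """Simulated recordings + metadata + the planted ground truth."""

    recordings: list[Recording]
    metadata: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def _normalize_map(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    return v / np.linalg.norm(v)


def make_templates(n_channels: int, seed: int = 0) -> list[TopographyTemplate]:
    """Four canonical microstate-style maps on the disc montage.

    A and B are saturated diagonal gradients (left-posterior to
    right-anterior and right-posterior to left-anterior), C an
    anterior-posterior gradient and D a radial fronto-central focus.  A
    small seeded per-channel jitter breaks the exact montage symmetry, and
    the four raw gradients are symmetrically (Loewdin) orthogonalized --
    the orthonormal set closest to the raw gradients -- so each planted
    state carries spatial information the others do not.
    """
    pos = disc_positions(n_channels)
    x, y = pos[:, 0], pos[:, 1]
    rng = np.random.default_rng(seed)
    raw = np.stack(
        [
            np.tanh(2.0 * (x + y) / math.sqrt(2.0)),
            np.tanh(2.0 * (y - x) / math.sqrt(2.0)),
            np.tanh(2.0 * y),
            np.exp(-((x ** 2 + (y - 0.45) ** 2) / (2 * 0.35 ** 2))),
        ]
    )
    raw = raw + 0.04 * rng.standard_normal(raw.shape)
    raw = raw - raw.mean(axis=1, keepdims=True)
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    gram = raw @ raw.T
    vals, vecs = np.linalg.eigh(gram)
    if vals.min() < 1e-6:
        raise ValueError(
            f"montage with {n_channels} channels cannot resolve four "
            "distinct gradients (degenerate template overlap)"
        )
    inv_sqrt = vecs @ np.diag(vals ** -0.5) @ vecs.T
    maps = [_normalize_map(m) for m in inv_sqrt @ raw]
    return [TopographyTemplate(m, lab) for m, lab in zip(maps, STATE_NAMES)]


# ---------------------------------------------------------------------------
# label sequence and signal
# ---------------------------------------------------------------------------

def simulate_label_sequence(
    spec: MarkovSpec,
    fs: float,
    n_samples: int,
    rng: np.random.Generator | None = None,
) -> LabelSequence:
    """Sample a microstate label per time point from the Markov dwell model.

    Dwell lengths are geometric (support >= 1 sample) with the per-state
    mean converted to samples; successive segment labels follow the
    transition matrix; the first label is uniform.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    k = spec.n_states
    mean_samples = spec.mean_durations_ms * fs / 1000.0
    p_end = np.minimum(1.0, 1.0 / mean_samples)
    labels = np.empty(n_samples, dtype=np.int64)
    state = int(rng.integers(k))
    pos = 0
    while pos < n_samples:
        dwell = int(rng.geometric(p_end[state]))
        end = min(pos + dwell, n_samples)
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(k, p=spec.transition_matrix[state]))
    return LabelSequence(labels=labels, fs=fs, n_states=k)


def _segment_starts(labels: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    return np.concatenate([[0], change])


def microstate_carrier(
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    freqs_hz: tuple[float, float] = (10.3, 6.7),
    mix: float = 0.6,
) -> np.ndarray:
    """Signed oscillatory time course carrying the microstate topography.

    A dominant alpha tone plus a weaker theta tone with random phases,
    normalized to unit RMS.  An oscillatory carrier keeps the microstate
    signal's spectrum at the carrier frequencies (broadened by the ~2 Hz
    segment-switching bandwidth), i.e. safely inside a 1-45 Hz band-pass;
    a slow or rectified envelope would park most of the topography's power
    below ~2 Hz, where the preprocessing high-pass destroys it.  The
    two-tone beat gives the waxing-and-waning global field power typical of
    resting EEG, and the incommensurate tones keep near-zero field samples
    rare and isolated.
    """
    t = np.arange(n_samples) / fs
    phi = rng.uniform(0.0, 2 * math.pi, size=2)
    c = np.sin(2 * math.pi * freqs_hz[0] * t + phi[0])
    c = c + mix * np.sin(2 * math.pi * freqs_hz[1] * t + phi[1])
    return c / np.sqrt(np.mean(c ** 2))


def synthesize_recording(
    labels: LabelSequence,
    templates: list[TopographyTemplate],
    noise_sd: float,
    band_effects: list[tuple[np.ndarray, float, float]] | None = None,
    seed: int = 0,
    amplitude_uv: float = 40.0,
    transition_ms: float = 0.0,
) -> Recording:
    """Render a label sequence into a multichannel voltage trace.

    ``V(t) = s_seg * amplitude * c(t) * T_{L(t)} + band oscillations +
    white noise``, where ``c(t)`` is the unit-RMS oscillatory carrier of
    :func:`microstate_carrier` and ``s_seg`` a random polarity per
    microstate segment (so analysis must be polarity invariant).
    ``band_effects`` is a list of ``(channel_mask, freq_hz, amplitude_uv)``
    sinusoids with a random phase per channel.

    With ``transition_ms`` > 0 the per-sample map sequence is smoothed by a
    raised-cosine kernel of that width, replacing instantaneous template and
    polarity switches with short crossfades.  The default (0) is the ideal
    piecewise model, where every nonzero sample is exactly a scaled ±map;
    the crossfade is what scalp data looks like after band-limiting, and
    keeps a band-pass filter from ringing at segment boundaries.
    """
    n_ch = templates[0].values.size
    if any(t.values.size != n_ch for t in templates):
        raise ValueError("templates disagree on channel count")
    rng = np.random.default_rng(seed)
    lab = labels.labels
    n = lab.size
    tmpl = np.stack([t.values for t in templates])
    if lab.max() >= tmpl.shape[0]:
        raise ValueError("label index exceeds number of templates")

    starts = _segment_starts(lab)
    seg_sign = rng.choice([-1.0, 1.0], size=starts.size)
    sign = np.repeat(seg_sign, np.diff(np.concatenate([starts, [n]])))

    carrier = microstate_carrier(n, labels.fs, rng)
    map_course = tmpl[lab] * sign[:, None]
    if transition_ms > 0:
        width = int(round(transition_ms * labels.fs / 1000.0))
        width += 1 - width % 2
        if width >= 3:
            from scipy.signal import fftconvolve
            from scipy.signal.windows import hann

            kernel = hann(width + 2)[1:-1]
            kernel /= kernel.sum()
            half = width // 2
            padded = np.pad(map_course, [(half, half), (0, 0)], mode="edge")
            map_course = fftconvolve(
                padded, kernel[:, None], mode="same", axes=0
            )[half:-half]
    data = map_course.T * (amplitude_uv * carrier)

    if band_effects:
        t = np.arange(n) / labels.fs
        for mask, freq, amp in band_effects:
            mask = np.asarray(mask, dtype=bool)
            if mask.size != n_ch:
                raise ValueError("band-effect mask has wrong channel count")
            if amp <= 0:
                continue
            phases = rng.uniform(0, 2 * math.pi, size=int(mask.sum()))
            osc = amp * np.sin(2 * math.pi * freq * t[None, :] + phases[:, None])
            data[mask] += osc
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    return Recording(
        data=data,
        fs=labels.fs,
        channel_names=channel_names(n_ch),
        reference="average" if noise_sd == 0 and not band_effects else "original",
        history=["synthesize_recording"],
    )


# ---------------------------------------------------------------------------
# group-level planted dynamics
# ---------------------------------------------------------------------------

def _renormalize(tm: np.ndarray) -> np.ndarray:
    tm = np.clip(tm, 0.0, None)
    np.fill_diagonal(tm, 0.0)
    return tm / tm.sum(axis=1, keepdims=True)


def uniform_transition_matrix(k: int = 4) -> np.ndarray:
    tm = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(tm, 0.0)
    return tm


def group_markov_specs(spec: CohortSpec) -> dict[str, MarkovSpec]:
    """The planted Markov model per group ('HC', 'ADHD-C', 'ADHD-I')."""
    A, B, C, D = 0, 1, 2, 3
    base = uniform_transition_matrix(4)

    def shifted(tm, pairs, delta):
        tm = tm.copy()
        for i, j in pairs:
            tm[i, j] += delta
        return tm

    hc_tm = base.copy()
    adhd_tm = shifted(base, [(A, C), (C, A)], -spec.trans_delta)
    adhd_tm = shifted(adhd_tm, [(B, D), (D, B)], +spec.trans_delta)
    adhd_tm[:, C] *= 1.0 - spec.c_inflow_scale
    adhd_tm = _renormalize(adhd_tm)

    c_tm = shifted(adhd_tm, [(A, C), (C, A)], -spec.subtype_trans_delta)
    c_tm = shifted(c_tm, [(B, D), (D, B)], +spec.subtype_trans_delta)
    c_tm[:, B] *= 1.0 + spec.b_inflow_scale
    c_tm = _renormalize(c_tm)

    d0 = spec.mean_duration_ms
    return {
        "HC": MarkovSpec(np.full(4, d0), _renormalize(hc_tm), seed=spec.seed),
        "ADHD-I": MarkovSpec(
            np.array([d0, d0, d0, spec.adhd_d_duration_ms]), adhd_tm, seed=spec.seed
        ),
        "ADHD-C": MarkovSpec(
            np.array([spec.adhd_c_a_duration_ms, d0, d0, spec.adhd_d_duration_ms]),
            c_tm,
            seed=spec.seed,
        ),
    }


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

_SCORE_NORMALS = {
    # (inattention, hyperactivity/impulsivity, total) as (mean, sd)
    "HC": ((15.14, 3.70), (11.79, 2.48), (26.93, 5.03)),
    "ADHD-C": ((27.58, 3.12), (24.60, 5.70), (52.18, 7.02)),
    "ADHD-I": ((27.16, 2.99), (17.52, 5.10), (44.69, 6.48)),
}
_SEX_MALE_FRAC = {"HC": 40 / 54, "ADHD-C": 42 / 51, "ADHD-I": 42 / 54}
_LEFT_HAND_FRAC = {"HC": 0.0, "ADHD-C": 8 / 107, "ADHD-I": 8 / 107}
_AGE_NORMALS = {"HC": (11.6, 1.81), "ADHD-C": (11.6, 1.57), "ADHD-I": (11.6, 2.02)}


def _sample_metadata(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counts = {"HC": spec.n_hc, "ADHD-C": spec.n_adhd_c, "ADHD-I": spec.n_adhd_i}
    idx = 0
    for cell, n in counts.items():
        group = "HC" if cell == "HC" else "ADHD"
        subtype = "" if cell == "HC" else cell.split("-")[1]
        n_male = int(round(_SEX_MALE_FRAC[cell] * n))
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sexes)
        n_left = int(round(_LEFT_HAND_FRAC[cell] * n))
        hands = np.array(["L"] * n_left + ["R"] * (n - n_left))
        rng.shuffle(hands)
        mu, sd = _AGE_NORMALS[cell]
        ages = np.clip(rng.normal(mu, sd, size=n), 8.0, 15.0)
        scores = [
            np.clip(rng.normal(m, s, size=n), 0.0, 54.0)
            for m, s in _SCORE_NORMALS[cell]
        ]
        for i in range(n):
            idx += 1
            rows.append(
                {
                    "subject_id": f"S{idx:03d}",
                    "group": group,
                    "subtype": subtype,
                    "sex": sexes[i],
                    "age": round(float(ages[i]), 1),
                    "hand": hands[i],
                    "inatt_score": round(float(scores[0][i]), 1),
                    "hyper_score": round(float(scores[1][i]), 1),
                    "total_score": round(float(scores[2][i]), 1),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate one recording per subject plus metadata and ground truth.

    Per-subject randomness is drawn from independent child streams of the
    cohort seed, so the cohort is bit-reproducible and individual subjects
    do not depend on cohort ordering.
    """
    ss = np.random.SeedSequence(spec.seed)
    meta_ss, template_ss, subj_root = ss.spawn(3)
    templates = make_templates(
        spec.n_channels, seed=int(template_ss.generate_state(1)[0] % (2 ** 31))
    )
    metadata = _sample_metadata(spec, np.random.default_rng(meta_ss))
    markov = group_markov_specs(spec)
    pos = disc_positions(spec.n_channels)
    masks = {
        name: region_mask(name, pos)
        for name in ("fronto-central", "fronto-temporal", "posterior-occipital")
    }
    n_samples = int(round(spec.duration_s * spec.fs))

    recordings: list[Recording] = []
    band_amps = {"delta": [], "theta": [], "gamma": []}
    children = subj_root.spawn(len(metadata))
    for row, child in zip(metadata.itertuples(index=False), children):
        cell = "HC" if row.group == "HC" else f"ADHD-{row.subtype}"
        rng = np.random.default_rng(child)
        lab = simulate_label_sequence(markov[cell], spec.fs, n_samples, rng=rng)
        is_adhd = cell != "HC"
        amp_delta = spec.delta_base_uv + (spec.delta_shift_uv if is_adhd else 0.0)
        amp_theta = spec.theta_base_uv + (spec.theta_shift_uv if is_adhd else 0.0)
        amp_gamma = spec.gamma_base_uv + (
            spec.gamma_shift_uv if cell == "ADHD-C" else 0.0
        )
        amps = {
            "delta": max(0.0, amp_delta + spec.subject_amp_sd * rng.standard_normal()),
            "theta": max(0.0, amp_theta + spec.subject_amp_sd * rng.standard_normal()),
            "gamma": max(0.0, amp_gamma + spec.subject_amp_sd * rng.standard_normal()),
        }
        for band in band_amps:
            band_amps[band].append(amps[band])
        effects = [
            (masks["fronto-central"], BAND_CENTER_HZ["delta"], amps["delta"]),
            (masks["fronto-temporal"], BAND_CENTER_HZ["theta"], amps["theta"]),
            (masks["posterior-occipital"], BAND_CENTER_HZ["gamma"], amps["gamma"]),
        ]
        rec = synthesize_recording(
            lab,
            templates,
            noise_sd=spec.noise_sd,
            band_effects=effects,
            seed=int(child.generate_state(4)[3] % (2 ** 31)),
            amplitude_uv=spec.amplitude_uv,
            transition_ms=spec.transition_ms,
        )
        recordings.append(rec)

    truth = {
        "templates": templates,
        "markov": markov,
        "region_masks": masks,
        "band_amplitudes": {
            band: np.asarray(vals) for band, vals in band_amps.items()
        },
        "spec": spec,
    }
    return Cohort(recordings=recordings, metadata=metadata, truth=truth)
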