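"""Synthetic resting-state EEG with known microstate ground truth.

The generator emulates the kind of data the pipeline targets: 64-channel,
250 Hz recordings of >= 200 s (configurable) whose scalp topography
alternates among four semi-stable prototype maps with mean dwell times in
the 60-120 ms range, random per-segment polarity, a smoothly varying
amplitude envelope (so the GFP has genuine local maxima), and additive
Gaussian sensor noise.

Segment dynamics follow a semi-Markov chain: successive segment classes
are drawn from a zero-diagonal transition matrix, and dwell times from a
shifted geometric law ``dwell = floor + Geometric(p)`` whose mean matches
the configured per-class mean.  The floor (default 32 ms) guarantees the
generated ground truth itself satisfies the quasi-stability the 30 ms
smoothing stage enforces, so recovery tests compare like with like; set
``min_dwell_ms=0`` for the plain geometric law.

The cohort generator plants the group effect and the clinical-scale
couplings the statistics layer is meant to detect: a reduced mean duration
of class C in the patient group, a positive coupling between the C->D
transition probability and an FMA-like motor score, and a negative
coupling between the duration of class A and a lower-limb-like score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .containers import (
    EEGRecording,
    LabelSequence,
    MicrostateFeatures,
    PrototypeSet,
    SubjectMeta,
    normalize_rows,
    spatial_correlation,
)
from .features import compute_features
from .layout import sensor_layout, smooth_basis
from .segmentation import compute_gfp

logger = logging.getLogger(__name__)

#: Default per-class mean dwell times (ms), taken from an illustrative
#: single-subject feature table (classes A-D).
DEFAULT_MEAN_DURATIONS_MS = (79.1481, 85.1345, 92.6626, 67.9401)

#: Relative segment frequencies matching the same table's occurrence row.
DEFAULT_CLASS_WEIGHTS = (3.0817, 3.3100, 3.7209, 1.9061)


def default_transition_matrix(k: int = 4, weights=DEFAULT_CLASS_WEIGHTS) -> np.ndarray:
    """Zero-diagonal stochastic matrix whose segment chain visits class
    ``j`` with frequency roughly proportional to ``weights[j]``:
    ``tp[i, j] = pi_j / (1 - pi_i)`` for ``j != i``."""
    w = np.asarray(weights, dtype=float)[:k]
    pi = w / w.sum()
    tp = np.tile(pi, (k, 1))
    np.fill_diagonal(tp, 0.0)
    tp /= tp.sum(axis=1, keepdims=True)
    return tp


def validate_transition_matrix(tp: np.ndarray) -> np.ndarray:
    tp = np.asarray(tp, dtype=float)
    if tp.ndim != 2 or tp.shape[0] != tp.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(np.abs(np.diag(tp)) > 0):
        raise ValueError("transition matrix diagonal must be exactly zero")
    if np.any(tp < 0) or np.any(np.abs(tp.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each transition-matrix row must sum to 1")
    return tp


@dataclass
class SyntheticConfig:
    """Single-recording generation parameters (the study conditions)."""

    n_channels: int = 64
    fs: float = 250.0
    duration: float = 200.0            # seconds
    k_true: int = 4
    mean_durations_ms: tuple = DEFAULT_MEAN_DURATIONS_MS
    tp_true: np.ndarray | None = None
    gfp_level: float = 1.0
    noise_sigma: float = 0.3           # sensor-noise sd relative to signal RMS
    polarity_flip_prob: float = 0.5    # per segment
    min_dwell_ms: float = 32.0         # dwell-law floor; 0 = plain geometric
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if len(self.mean_durations_ms) < self.k_true:
            raise ValueError("need a mean duration per class")
        if any(d <= 0 for d in self.mean_durations_ms[: self.k_true]):
            raise ValueError("mean durations must be positive")
        if self.tp_true is None:
            self.tp_true = default_transition_matrix(self.k_true)
        self.tp_true = validate_transition_matrix(self.tp_true)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class CohortConfig:
    """Two-group cohort with planted effects.

    Classes are indexed 0-3 and referred to as A-D in planted-effect names
    (the group difference sits on class 2 = "C", the scale couplings on the
    C->D transition and on class 0 = "A").
    """

    n_per_group: int = 12
    dur_c_effect_ms: float = 25.0       # patient-group reduction of mean Dur_C
    dur_between_sd_ms: float = 15.0     # between-subject sd of each mean duration
    tp_cd_slope: float = 0.05           # d(p_CD) per sd of the FMA-like score
    tp_cd_noise_sd: float = 0.045
    dur_a_slope: float = -6.0           # d(Dur_A)/sd of lower-limb-like score, ms
    dur_a_noise_sd: float = 7.2
    age_patient: tuple = (59.8, 12.8)   # mean, sd (years)
    age_healthy: tuple = (29.0, 7.1)
    seed: int = 0


def make_prototypes(
    n_channels: int,
    k: int,
    seed: int,
    max_abs_corr: float = 0.5,
    max_draws: int = 2000,
) -> PrototypeSet:
    """Draw ``k`` smooth, mutually distinct topographies.

    Maps are random combinations of low-order polynomial patterns over the
    sensor layout plus a little unstructured texture, zero-meaned and
    unit-normed.  Candidates are rejected until every accepted pair has
    ``|spatial correlation| <= max_abs_corr``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_channels < max(2, k):
        raise ValueError(f"{n_channels} channels cannot carry {k} distinct zero-mean maps")
    rng = np.random.default_rng(seed)
    basis = smooth_basis(sensor_layout(n_channels), degree=3)
    accepted: list[np.ndarray] = []
    for _ in range(max_draws):
        m = basis @ rng.standard_normal(basis.shape[1])
        m = m + 0.05 * np.linalg.norm(m) / np.sqrt(n_channels) * rng.standard_normal(n_channels)
        m = normalize_rows(m[None, :])[0]
        if accepted:
            corr = spatial_correlation(m[None, :], np.vstack(accepted))
            if np.max(np.abs(corr)) > max_abs_corr:
                continue
        accepted.append(m)
        if len(accepted) == k:
            return PrototypeSet(maps=np.vstack(accepted))
    raise RuntimeError(
        f"could not draw {k} maps with pairwise |corr| <= {max_abs_corr} "
        f"in {max_draws} attempts"
    )


def stationary_distribution(tp: np.ndarray) -> np.ndarray:
    """Stationary segment-class frequencies of the transition chain."""
    vals, vecs = np.linalg.eig(tp.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_label_sequence(
    tp: np.ndarray,
    mean_durations_ms,
    fs: float,
    n_samples: int,
    seed: int,
    min_dwell_ms: float = 32.0,
) -> LabelSequence:
    """Semi-Markov microstate label sequence.

    Segment classes follow ``tp`` (successive labels always differ since
    the diagonal is zero); dwell times are ``floor + Geometric(p)`` in
    samples with the configured per-class mean.  The first class is drawn
    from the chain's stationary distribution; the last segment is
    truncated at ``n_samples``.
    """
    tp = validate_transition_matrix(tp)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    k = tp.shape[0]
    means = np.asarray(mean_durations_ms, dtype=float)[:k] * fs / 1000.0
    floor = int(np.ceil(min_dwell_ms * fs / 1000.0)) if min_dwell_ms > 0 else 0
    # E[dwell] = floor + 1/p  ->  p = 1 / (mean - floor); degenerate means pin p = 1
    p = np.clip(1.0 / np.maximum(means - floor, 1.0), None, 1.0)

    rng = np.random.default_rng(seed)
    labels = np.empty(n_samples, dtype=int)
    cum = np.cumsum(tp, axis=1)
    c = int(rng.choice(k, p=stationary_distribution(tp)))
    t = 0
    while t < n_samples:
        dwell = floor + rng.geometric(p[c])
        stop = min(t + dwell, n_samples)
        labels[t:stop] = c
        t = stop
        c = int(np.searchsorted(cum[c], rng.random(), side="right"))
    return LabelSequence(labels=labels, fs=fs)


def simulate_eeg(
    prototypes: PrototypeSet,
    seq: LabelSequence,
    gfp_level: float = 1.0,
    noise_sigma: float = 0.3,
    polarity_flip_prob: float = 0.5,
    seed: int = 0,
) -> EEGRecording:
    """Render a label sequence into multichannel EEG.

    Each sample is ``s(t) * a(t) * map[label(t)] + noise``: ``s`` is a
    per-segment polarity (+-1, flipping between consecutive segments with
    ``polarity_flip_prob``), ``a`` a rectified smoothed-noise amplitude
    envelope scaled so the clean signal's mean GFP equals ``gfp_level``,
    and the noise is i.i.d. Gaussian per channel with sd
    ``noise_sigma * gfp_level`` (i.e. relative to the mean signal RMS).
    The output is common-average referenced.
    """
    rng = np.random.default_rng(seed)
    n = len(seq)
    nch = prototypes.n_channels
    maps = normalize_rows(prototypes.maps)

    env = np.abs(gaussian_filter1d(rng.standard_normal(n), sigma=max(1.0, 0.02 * seq.fs)))
    env = env + 0.1 * env.mean()
    amp = env / env.mean() * gfp_level * np.sqrt(nch)

    segs = seq.segments()
    sign = np.ones(n)
    s = 1.0
    for i, seg in enumerate(segs):
        if i > 0 and rng.random() < polarity_flip_prob:
            s = -s
        sign[seg.start:seg.stop] = s

    data = np.zeros((nch, n))
    ok = seq.labels >= 0
    data[:, ok] = maps[seq.labels[ok]].T * (sign[ok] * amp[ok])
    if noise_sigma > 0:
        data += rng.normal(0.0, noise_sigma * gfp_level, size=data.shape)
    data -= data.mean(axis=0, keepdims=True)
    return EEGRecording(data=data, fs=seq.fs)


@dataclass
class SyntheticSubject:
    """One simulated subject: recording, metadata and planted ground truth."""

    meta: SubjectMeta
    params: dict                       # planted per-subject mean durations / tp
    recording: EEGRecording | None
    true_labels: LabelSequence
    true_features: MicrostateFeatures


def _subject_scores(rng: np.random.Generator) -> dict:
    upper = float(np.clip(rng.normal(40.0, 12.0), 5, 66))
    lower = float(np.clip(rng.normal(20.0, 7.0), 3, 34))
    return {
        "fma_upper": round(upper, 1),
        "fma_lower": round(lower, 1),
        "fma_total": round(upper + lower, 1),
        "iadl": float(np.clip(np.round(rng.normal(5.0, 2.0)), 0, 8)),
    }


def _plant_tp(base_tp: np.ndarray, p_cd: float) -> np.ndarray:
    """Set the C->D entry and renormalize the rest of row C."""
    tp = base_tp.copy()
    clipped = np.clip(p_cd, 0.02, 0.9)
    if clipped != p_cd:
        logger.warning("planted C->D probability %.3f clipped to %.3f", p_cd, clipped)
    row = tp[2].copy()
    others = row.sum() - row[3]
    row[3] = clipped
    scale = (1.0 - clipped) / others if others > 0 else 0.0
    for j in range(len(row)):
        if j not in (2, 3):
            row[j] *= scale
    row[2] = 0.0
    tp[2] = row / row.sum()
    return tp


def plant_subject_parameters(cfg: CohortConfig, base: SyntheticConfig, rng: np.random.Generator,
                             group: str) -> tuple[dict, dict]:
    """Draw one subject's metadata scores and planted generator parameters."""
    k = base.k_true
    scores = _subject_scores(rng) if group == "patient" else {}
    durs = np.array(base.mean_durations_ms[:k], dtype=float)
    durs = durs + rng.normal(0.0, cfg.dur_between_sd_ms, size=k)
    if group == "patient":
        durs[2] -= cfg.dur_c_effect_ms
        z_lower = (scores["fma_lower"] - 20.0) / 7.0
        durs[0] = (
            base.mean_durations_ms[0]
            + cfg.dur_a_slope * z_lower
            + rng.normal(0.0, cfg.dur_a_noise_sd)
        )
    low = max(40.0, base.min_dwell_ms + 8.0)
    if np.any(durs < low):
        logger.warning("planted durations clipped to >= %.0f ms", low)
        durs = np.maximum(durs, low)

    base_cd = base.tp_true[2, 3]
    if group == "patient":
        z_fma = (scores["fma_total"] - 60.0) / 14.0
        p_cd = base_cd + cfg.tp_cd_slope * z_fma + rng.normal(0.0, cfg.tp_cd_noise_sd)
    else:
        p_cd = base_cd + rng.normal(0.0, cfg.tp_cd_noise_sd)
    tp = _plant_tp(base.tp_true, p_cd)
    return scores, {"mean_durations_ms": durs, "tp": tp}


def simulate_cohort(
    cfg: CohortConfig,
    base: SyntheticConfig | None = None,
    render_eeg: bool = True,
) -> tuple[list[SyntheticSubject], PrototypeSet]:
    """Simulate a two-group cohort sharing one generating prototype set.

    Returns the subject list and the generating prototypes.  With
    ``render_eeg=False`` only label sequences and ground-truth features are
    produced (fast path for statistics simulations).
    """
    if base is None:
        base = SyntheticConfig()
    prototypes = make_prototypes(base.n_channels, base.k_true, seed=base.seed)
    master = np.random.SeedSequence(cfg.seed)
    subjects: list[SyntheticSubject] = []
    groups = ["patient"] * cfg.n_per_group + ["healthy"] * cfg.n_per_group
    for i, (group, ss) in enumerate(zip(groups, master.spawn(len(groups)))):
        rng = np.random.default_rng(ss)
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        scores, params = plant_subject_parameters(cfg, base, rng, group)
        age_mu, age_sd = cfg.age_patient if group == "patient" else cfg.age_healthy
        meta = SubjectMeta(
            subject_id=f"{'P' if group == 'patient' else 'H'}{i + 1:02d}",
            group=group,
            age=float(np.clip(rng.normal(age_mu, age_sd), 18, 90)),
            sex="M" if rng.random() < 0.7 else "F",
            **(scores if group == "patient" else {}),
        )
        seq = simulate_label_sequence(
            params["tp"], params["mean_durations_ms"], base.fs, base.n_samples,
            seed=sub_seed, min_dwell_ms=base.min_dwell_ms,
        )
        rec = None
        gfp = None
        if render_eeg:
            rec = simulate_eeg(
                prototypes, seq,
                gfp_level=base.gfp_level, noise_sigma=base.noise_sigma,
                polarity_flip_prob=base.polarity_flip_prob, seed=sub_seed + 1,
            )
            rec.subject_id = meta.subject_id
            gfp = compute_gfp(rec)
        feats = compute_features(seq, gfp=gfp, k=base.k_true,
                                 class_labels=list("ABCD")[: base.k_true])
        subjects.append(SyntheticSubject(
            meta=meta, params=params, recording=rec,
            true_labels=seq, true_features=feats,
        ))
    return subjects, prototypes


def simulate_feature_cohort(cfg: CohortConfig, base: SyntheticConfig | None = None,
                            seed: int | None = None) -> pd.DataFrame:
    """Parameter-level cohort table (no EEG, no label sequences).

    One row per subject with the *planted* per-class mean durations and the
    planted C->D transition probability, plus metadata and scale scores.
    This is the fast path for type-I-error and power simulations of the
    statistics layer, where only the planted between-subject structure
    matters.
    """
    if base is None:
        base = SyntheticConfig()
    if seed is None:
        seed = cfg.seed
    master = np.random.SeedSequence(seed)
    rows = []
    groups = ["patient"] * cfg.n_per_group + ["healthy"] * cfg.n_per_group
    for i, (group, ss) in enumerate(zip(groups, master.spawn(len(groups)))):
        rng = np.random.default_rng(ss)
        scores, params = plant_subject_parameters(cfg, base, rng, group)
        age_mu, age_sd = cfg.age_patient if group == "patient" else cfg.age_healthy
        row = {
            "subject_id": f"{'P' if group == 'patient' else 'H'}{i + 1:02d}",
            "group": group,
            "age": float(np.clip(rng.normal(age_mu, age_sd), 18, 90)),
            "sex": "M" if rng.random() < 0.7 else "F",
            **{k: scores.get(k) for k in ("fma_total", "fma_upper", "fma_lower", "iadl")},
        }
        for c, name in enumerate("ABCD"[: base.k_true]):
            row[f"Dur_{name}"] = float(params["mean_durations_ms"][c])
        row["C-D"] = float(params["tp"][2, 3])
        rows.append(row)
    return pd.DataFrame(rows)
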