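"""Core in-memory containers shared by every pipeline stage.

All containers are thin dataclasses around numpy arrays.  Conventions:

* EEG data is ``channels x samples`` in microvolts (or normalized units
  after :func:`eegmicrostates.preprocess.normalize_global`).
* Topographic maps ("prototypes", "peak maps") are row vectors of length
  ``n_channels``; clustering and back-fitting treat them polarity-free,
  i.e. a map and its negation are the same microstate.
* Microstate class labels are integers ``0..k-1``; the sentinel ``-1``
  marks samples that could not be assigned (flat, zero-variance maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

UNASSIGNED = -1


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data[ch, t]`` potentials with sampling rate ``fs``."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "EEGRecording":
        return replace(self, **kwargs)


@dataclass
class GFPSeries:
    """Global field power: spatial standard deviation per time sample."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PeakMaps:
    """Topographies extracted at GFP local maxima ("original maps")."""

    maps: np.ndarray            # n_peaks x n_channels
    peak_indices: np.ndarray    # sample index of each peak, strictly increasing
    peak_gfp: np.ndarray        # GFP amplitude at each peak

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.peak_gfp = np.asarray(self.peak_gfp, dtype=float)
        if self.maps.size == 0:
            self.maps = self.maps.reshape(0, self.maps.shape[-1] if self.maps.ndim == 2 else 0)
        n = self.maps.shape[0]
        if len(self.peak_indices) != n or len(self.peak_gfp) != n:
            raise ValueError("peak_indices / peak_gfp length must match map count")
        if n > 1 and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return self.maps.shape[0]


@dataclass
class PrototypeSet:
    """``k`` zero-mean unit-norm microstate topographies plus fit diagnostics.

    ``labels`` holds the canonical class names (``A``–``D`` for k = 4) once
    :func:`eegmicrostates.clustering.label_prototypes` has been applied;
    before that it is ``None`` and classes are addressed by index.
    """

    maps: np.ndarray                       # k x n_channels
    labels: list[str] | None = None
    gev_per_class: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.labels is not None and len(self.labels) != self.k:
            raise ValueError("label count must equal k")
        if self.gev_per_class is not None:
            self.gev_per_class = np.asarray(self.gev_per_class, dtype=float)

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def class_names(self) -> list[str]:
        if self.labels is not None:
            return list(self.labels)
        return [str(i) for i in range(self.k)]


@dataclass
class Segment:
    """One maximal run of a single microstate class."""

    label: int
    start: int
    length: int

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass
class LabelSequence:
    """Per-sample microstate labels (``-1`` = unassigned).

    ``similarity`` optionally stores the ``n_samples x k`` matrix of absolute
    spatial correlations produced by back-fitting; temporal smoothing uses it
    to decide which flank absorbs a rejected short segment.
    """

    labels: np.ndarray
    fs: float
    similarity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.similarity is not None:
            self.similarity = np.asarray(self.similarity, dtype=float)
            if self.similarity.shape[0] != len(self.labels):
                raise ValueError("similarity rows must match label count")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        lab = self.labels[self.labels >= 0]
        return int(lab.max()) + 1 if lab.size else 0

    def segments(self) -> list[Segment]:
        """Run-length encode the labeled spans (unassigned runs are skipped)."""
        segs: list[Segment] = []
        lab = self.labels
        n = len(lab)
        t = 0
        while t < n:
            if lab[t] == UNASSIGNED:
                t += 1
                continue
            start = t
            while t < n and lab[t] == lab[start]:
                t += 1
            segs.append(Segment(int(lab[start]), start, t - start))
        return segs


@dataclass
class MicrostateFeatures:
    """Per-class microstate features and the transition-probability matrix.

    * ``dur``      mean segment duration per class, ms
    * ``occ``      segment onsets per second of labeled time, 1/s
    * ``cov``      fraction of labeled samples per class (sums to 1)
    * ``mean_gfp`` mean GFP while the class dominates
    * ``tp``       ``k x k`` row-stochastic matrix of segment transitions,
      zero diagonal; a row is all-zero if its class never transitions
    """

    dur: np.ndarray
    occ: np.ndarray
    cov: np.ndarray
    mean_gfp: np.ndarray
    tp: np.ndarray
    class_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.dur = np.asarray(self.dur, dtype=float)
        self.occ = np.asarray(self.occ, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        self.mean_gfp = np.asarray(self.mean_gfp, dtype=float)
        self.tp = np.asarray(self.tp, dtype=float)
        k = len(self.dur)
        if self.tp.shape != (k, k):
            raise ValueError("tp must be k x k")

    @property
    def k(self) -> int:
        return len(self.dur)

    def class_names(self) -> list[str]:
        if self.class_labels is not None:
            return list(self.class_labels)
        return [str(i) for i in range(self.k)]


@dataclass
class SubjectMeta:
    """Per-subject metadata and clinical scale scores.

    Scale scores (FMA total / upper-limb / lower-limb, IADL) are collected
    for patients only; healthy subjects carry ``None``.
    """

    subject_id: str
    group: str                      # "patient" | "healthy"
    age: float
    sex: str                        # "M" | "F"
    fma_total: float | None = None
    fma_upper: float | None = None
    fma_lower: float | None = None
    iadl: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "healthy"):
            raise ValueError(f"group must be 'patient' or 'healthy', got {self.group!r}")
        if self.group == "patient":
            missing = [
                name
                for name in ("fma_total", "fma_upper", "fma_lower", "iadl")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(f"patient {self.subject_id}: missing scores {missing}")

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
            "fma_total": self.fma_total,
            "fma_upper": self.fma_upper,
            "fma_lower": self.fma_lower,
            "iadl": self.iadl,
        }


def zero_mean_rows(maps: np.ndarray) -> np.ndarray:
    """Remove the spatial mean from each map (average-reference the map)."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    return maps - maps.mean(axis=1, keepdims=True)


def normalize_rows(maps: np.ndarray) -> np.ndarray:
    """Zero-mean each map then scale to unit L2 norm (zero maps stay zero)."""
    maps = zero_mean_rows(maps)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spatial correlation between map sets, computed on zero-meaned maps.

    Equivalent to cosine similarity after common-average referencing; the
    matrix entry ``[i, j]`` correlates row ``i`` of ``a`` with row ``j`` of
    ``b``.  Zero-variance maps yield correlation 0.
    """
    an = normalize_rows(np.atleast_2d(a))
    bn = normalize_rows(np.atleast_2d(b))
    return an @ bn.T
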