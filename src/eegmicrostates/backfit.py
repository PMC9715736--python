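"""Back-fitting: label every EEG sample with its best-matching prototype,
then merge segments too short to be genuine microstates.

Assignment is winner-take-all on the absolute spatial correlation between
the instantaneous topography and each prototype (polarity-free, matching
the clustering stage).  Quasi-stability requires each microstate to persist
for tens of milliseconds, so segments shorter than ``min_duration_ms``
(default 30 ms) are treated as noise and absorbed into their flanks:
working from the shortest offending segment outward, each of its samples is
relabeled to whichever flanking class correlates better with that sample's
topography.  The procedure repeats until no interior segment is below
threshold; it is idempotent and conserves the total labeled duration.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .containers import (
    EEGRecording,
    LabelSequence,
    PrototypeSet,
    Segment,
    UNASSIGNED,
    normalize_rows,
)

logger = logging.getLogger(__name__)


def assign_labels(rec: EEGRecording, prototypes: PrototypeSet) -> LabelSequence:
    """Winner-take-all microstate label for every sample.

    Samples with a flat (zero-variance) topography get the ``-1`` sentinel
    and are excluded from all downstream features.  Ties break toward the
    lowest class index.  The absolute-correlation matrix is retained on the
    result for use by :func:`smooth_labels`.
    """
    if rec.n_channels != prototypes.n_channels:
        raise ValueError("channel count of recording and prototypes differ")
    x = rec.data - rec.data.mean(axis=0, keepdims=True)   # per-sample zero mean
    norms = np.linalg.norm(x, axis=0)
    flat = norms == 0
    safe = np.where(flat, 1.0, norms)
    proto = normalize_rows(prototypes.maps)
    sim = np.abs((x / safe).T @ proto.T)                  # n_samples x k
    labels = np.argmax(sim, axis=1)
    labels[flat] = UNASSIGNED
    sim[flat] = 0.0
    return LabelSequence(labels=labels, fs=rec.fs, similarity=sim)


def min_samples_for(min_duration_ms: float, fs: float) -> int:
    """Smallest segment length (samples) whose duration is >= the threshold."""
    return max(1, math.ceil(min_duration_ms * fs / 1000.0 - 1e-9))


def smooth_labels(
    seq: LabelSequence,
    min_duration_ms: float = 30.0,
    exempt_edges: bool = True,
) -> LabelSequence:
    """Absorb segments shorter than ``min_duration_ms`` into their flanks.

    Repeatedly selects the shortest sub-threshold segment (ties: earliest
    start) and relabels each of its samples to the flanking class with the
    higher stored absolute correlation at that sample (the segment's own
    class is excluded, so absorption always progresses).  Without a stored
    similarity matrix the segment is split at its midpoint between the two
    flanks.  Segments truncated by the record edge are exempt when
    ``exempt_edges`` is true; a record consisting of a single short segment
    is kept with a warning.
    """
    labels = seq.labels.copy()
    n = len(labels)
    min_len = min_samples_for(min_duration_ms, seq.fs)
    sim = seq.similarity

    def runs() -> list[Segment]:
        return LabelSequence(labels=labels, fs=seq.fs).segments()

    frozen: set[int] = set()   # starts of short segments with no flank to absorb into
    guard = 0
    max_rounds = 4 * max(1, len(runs())) + n
    while True:
        segs = runs()
        short = [
            (s.length, s.start, i)
            for i, s in enumerate(segs)
            if s.length < min_len
            and s.start not in frozen
            and not (exempt_edges and (s.start == 0 or s.stop == n))
        ]
        if not short:
            break
        guard += 1
        if guard > max_rounds:
            logger.warning("smoothing did not converge within %d rounds", max_rounds)
            break
        _, _, i = min(short)
        s = segs[i]
        left = segs[i - 1] if i > 0 and segs[i - 1].stop == s.start else None
        right = segs[i + 1] if i + 1 < len(segs) and segs[i + 1].start == s.stop else None
        if left is None and right is None:
            logger.warning(
                "segment at sample %d is shorter than the %g ms threshold but has "
                "no flank to absorb it; kept",
                s.start, min_duration_ms,
            )
            frozen.add(s.start)
            continue
        if left is None or right is None or left.label == right.label:
            target = left.label if left is not None else right.label
            labels[s.start:s.stop] = target
            continue
        idx = np.arange(s.start, s.stop)
        if sim is not None:
            take_left = sim[idx, left.label] >= sim[idx, right.label]
        else:
            take_left = idx - s.start < (s.length + 1) // 2
        labels[idx] = np.where(take_left, left.label, right.label)
    return LabelSequence(labels=labels, fs=seq.fs, similarity=seq.similarity)


def backfit(
    rec: EEGRecording,
    prototypes: PrototypeSet,
    min_duration_ms: float = 30.0,
    exempt_edges: bool = True,
) -> LabelSequence:
    """Assignment followed by temporal smoothing, in one call."""
    return smooth_labels(
        assign_labels(rec, prototypes),
        min_duration_ms=min_duration_ms,
        exempt_edges=exempt_edges,
    )
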