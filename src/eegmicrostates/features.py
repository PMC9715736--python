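"""Microstate features: duration, occurrence, coverage, mean GFP, and the
transition-probability matrix.

Definitions (per class ``c``, on a smoothed label sequence):

* ``Dur_c``  — mean length of class-``c`` segments, in ms;
* ``Occ_c``  — number of class-``c`` segment onsets per second of labeled
  time;
* ``Cov_c``  — fraction of labeled samples carrying label ``c``;
* ``GFP_c``  — mean global field power over class-``c`` samples;
* ``tp[i, j]`` — fraction of segment transitions leaving class ``i`` that
  enter class ``j``; the diagonal is identically zero because a microstate
  cannot transition to itself.

Occurrence counts segment onsets (not samples), which makes the internal
consistency identity ``Cov_c = Occ_c * Dur_c / 1000`` hold exactly; the
same identity holds to four decimals in published per-subject feature
tables (see ``EXAMPLE_PATIENT_FEATURES``).  Unassigned samples are
excluded from every denominator, and transitions are only counted between
segments that are temporally adjacent (no transition across an unassigned
gap).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GFPSeries, LabelSequence, MicrostateFeatures, SubjectMeta

#: Illustrative per-class features of a single stroke-patient recording,
#: used in documentation and internal-consistency tests (the product rule
#: Cov = Occ * Dur / 1000 reproduces the Cov row to 4 decimals).
EXAMPLE_PATIENT_FEATURES = pd.DataFrame(
    {
        "A": [2.5429, 3.0817, 79.1481, 0.2439],
        "B": [2.6814, 3.3100, 85.1345, 0.2818],
        "C": [2.9412, 3.7209, 92.6626, 0.3448],
        "D": [2.5121, 1.9061, 67.9401, 0.1295],
    },
    index=["GFP", "Occ", "Dur", "Cov"],
)

#: Column order of the 12 off-diagonal transition probabilities for k = 4.
TP_COLUMNS = [
    f"{a}-{b}" for a in "ABCD" for b in "ABCD" if a != b
]

FEATURE_COLUMNS = (
    [f"GFP_{c}" for c in "ABCD"]
    + [f"Occ_{c}" for c in "ABCD"]
    + [f"Dur_{c}" for c in "ABCD"]
    + [f"Cov_{c}" for c in "ABCD"]
    + TP_COLUMNS
)


def compute_features(
    seq: LabelSequence,
    gfp: GFPSeries | None = None,
    k: int | None = None,
    class_labels: list[str] | None = None,
) -> MicrostateFeatures:
    """Per-class features and transition matrix from a label sequence.

    ``k`` defaults to ``max(label) + 1``; classes that never occur get
    all-zero features (and an all-zero transition row).  ``gfp`` may be
    omitted, in which case the mean-GFP feature is reported as NaN.
    """
    segs = seq.segments()
    if not segs:
        raise ValueError("empty label sequence: no labeled samples")
    if k is None:
        k = seq.n_classes
    if gfp is not None and len(gfp) != len(seq):
        raise ValueError("GFP series length must match label sequence length")

    labeled = sum(s.length for s in segs)
    total_s = labeled / seq.fs

    dur = np.zeros(k)
    occ = np.zeros(k)
    cov = np.zeros(k)
    mean_gfp = np.full(k, np.nan)
    counts = np.zeros(k)
    samples = np.zeros(k)
    for s in segs:
        counts[s.label] += 1
        samples[s.label] += s.length
    present = counts > 0
    dur[present] = (samples[present] / counts[present]) * 1000.0 / seq.fs
    occ[present] = counts[present] / total_s
    cov[present] = samples[present] / labeled
    if gfp is not None:
        for c in range(k):
            mask = seq.labels == c
            mean_gfp[c] = float(gfp.values[mask].mean()) if mask.any() else 0.0

    trans = np.zeros((k, k))
    for a, b in zip(segs, segs[1:]):
        if a.stop == b.start:           # adjacent: a genuine transition
            trans[a.label, b.label] += 1
    np.fill_diagonal(trans, 0.0)        # adjacent same-class runs only occur across gaps
    tp = np.zeros((k, k))
    row_sums = trans.sum(axis=1)
    nz = row_sums > 0
    tp[nz] = trans[nz] / row_sums[nz, None]

    return MicrostateFeatures(
        dur=dur, occ=occ, cov=cov, mean_gfp=mean_gfp, tp=tp,
        class_labels=class_labels,
    )


def features_to_row(features: MicrostateFeatures, meta: SubjectMeta | dict | None = None) -> dict:
    """Flatten k = 4 features into the standard 28-column row.

    Columns: ``GFP_A..GFP_D, Occ_A.., Dur_A.., Cov_A..`` plus the 12
    ordered off-diagonal transition probabilities ``A-B, A-C, ..., D-C``,
    followed by any metadata fields.  Classes must be labeled A-D (apply
    :func:`eegmicrostates.clustering.label_prototypes` upstream) or
    unlabeled with exactly k = 4, in which case index order 0-3 maps to
    A-D.
    """
    if features.k != 4:
        raise ValueError("the 28-column layout is defined for k = 4 only")
    names = features.class_names()
    if features.class_labels is not None:
        if sorted(names) != ["A", "B", "C", "D"]:
            raise ValueError(f"class labels must be A-D, got {names}")
        order = [names.index(c) for c in "ABCD"]
    else:
        order = [0, 1, 2, 3]
    row: dict = {}
    for arr, prefix in [
        (features.mean_gfp, "GFP"),
        (features.occ, "Occ"),
        (features.dur, "Dur"),
        (features.cov, "Cov"),
    ]:
        for pos, c in zip(order, "ABCD"):
            row[f"{prefix}_{c}"] = float(arr[pos])
    for i, a in zip(order, "ABCD"):
        for j, b in zip(order, "ABCD"):
            if a != b:
                row[f"{a}-{b}"] = float(features.tp[i, j])
    if meta is not None:
        md = meta.as_dict() if isinstance(meta, SubjectMeta) else dict(meta)
        row.update(md)
    return row


def cohort_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-subject rows into a cohort table (one row per subject)."""
    df = pd.DataFrame(rows)
    feature_cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    other = [c for c in df.columns if c not in feature_cols]
    return df[other + feature_cols] if feature_cols else df
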