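"""Polarity-invariant ("modified") k-means over GFP-peak topographies.

Spontaneous EEG topographies recur with arbitrary polarity, so similarity
between a map ``x`` and a prototype ``p`` is the *squared* spatial
correlation, and the cluster centroid is not the mean but the dominant
eigenvector of the member maps' covariance — the direction that maximizes
the summed squared projection regardless of sign.  This pair of choices is
what distinguishes the microstate ("modified") k-means from the ordinary
algorithm.

Fit quality is measured by the global explained variance

    GEV = sum_i GFP_i^2 * corr^2(x_i, p_{a_i}) / sum_i GFP_i^2 ,

the GFP-weighted fraction of topographic variance captured by the assigned
prototypes.  ``scan_k`` additionally reports the classical model-order
diagnostics:

* ``cv`` — predictive-residual criterion: the residual noise variance
  estimate penalized by ``((C-1)/(C-1-k))^2``, ``C`` = channel count;
* ``w``  — within-cluster dispersion with the polarity-free dissimilarity
  ``d^2(x, y) = 1 - corr^2(x, y)``;
* ``kl`` — Krzanowski-Lai index built from successive differences of
  ``k^(2/m) W_k`` with ``m = C - 1`` effective dimensions.

These are diagnostics only; resting-state analyses conventionally fix
``k = 4`` for cross-study comparability.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import (
    PeakMaps,
    PrototypeSet,
    normalize_rows,
    spatial_correlation,
    zero_mean_rows,
)
from .layout import canonical_templates

logger = logging.getLogger(__name__)


def _as_maps_and_gfp(peaks: PeakMaps | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(peaks, PeakMaps):
        maps = peaks.maps
        gfp = peaks.peak_gfp
    else:
        maps = np.atleast_2d(np.asarray(peaks, dtype=float))
        gfp = maps.std(axis=1)  # spatial std = the map's own GFP
    return zero_mean_rows(maps), np.asarray(gfp, dtype=float)


def assign_peaks(peaks: PeakMaps | np.ndarray, prototypes: PrototypeSet) -> tuple[np.ndarray, np.ndarray]:
    """Winner-take-all assignment of peak maps to prototypes.

    Returns ``(assignment, corr)`` where ``corr`` is the ``n x k`` signed
    spatial-correlation matrix and ``assignment[i]`` maximizes
    ``corr[i] ** 2`` (ties broken toward the lowest class index).
    """
    maps, _ = _as_maps_and_gfp(peaks)
    corr = spatial_correlation(maps, prototypes.maps)
    return np.argmax(corr**2, axis=1), corr


def compute_gev(
    peaks: PeakMaps | np.ndarray,
    prototypes: PrototypeSet,
    assignment: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """GFP^2-weighted explained variance, total and partitioned per class."""
    maps, gfp = _as_maps_and_gfp(peaks)
    denom = float(np.sum(gfp**2))
    if denom == 0:
        raise ValueError("total GFP is zero; GEV undefined")
    if assignment is None:
        assignment, corr = assign_peaks(peaks, prototypes)
    else:
        assignment = np.asarray(assignment, dtype=int)
        corr = spatial_correlation(maps, prototypes.maps)
    contrib = gfp**2 * np.take_along_axis(corr**2, assignment[:, None], axis=1)[:, 0]
    per_class = np.array(
        [contrib[assignment == j].sum() for j in range(prototypes.k)]
    ) / denom
    return float(per_class.sum()), per_class


def _dominant_eigenvector(maps: np.ndarray) -> np.ndarray:
    """First principal axis of a set of zero-mean maps (unit norm)."""
    cov = maps.T @ maps
    _, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    v = v - v.mean()
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def modified_kmeans(
    peaks: PeakMaps | np.ndarray,
    k: int,
    n_restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
) -> PrototypeSet:
    """Fit ``k`` polarity-invariant prototypes to peak maps.

    Runs ``n_restarts`` independently initialized fits (prototypes seeded
    from randomly chosen peak maps) and keeps the one with the highest GEV.
    Iteration alternates winner-take-all assignment by squared correlation
    with the eigenvector centroid update, stopping when the GEV improves by
    less than ``tol`` or after ``max_iter`` sweeps.  An emptied cluster is
    re-seeded from the currently worst-explained peak map.

    Prototypes in the result are zero-mean, unit-norm, and ranked by their
    per-class GEV contribution (largest first).
    """
    if seed is None:
        raise ValueError("seed is required for reproducible clustering")
    maps, gfp = _as_maps_and_gfp(peaks)
    n = maps.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} peak maps, got {n}")
    maps_n = normalize_rows(maps)
    w2 = gfp**2
    denom = float(w2.sum())
    if denom == 0:
        raise ValueError("total GFP is zero")

    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for restart, child in enumerate(np.random.SeedSequence(seed).spawn(n_restarts)):
        rng = np.random.default_rng(child)
        proto = maps_n[rng.choice(n, size=k, replace=False)].copy()
        prev_gev = -np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            corr = maps_n @ proto.T
            assignment = np.argmax(corr**2, axis=1)
            picked = np.take_along_axis(corr**2, assignment[:, None], axis=1)[:, 0]
            for j in range(k):
                if not np.any(assignment == j):
                    worst = int(np.argmin(picked))
                    proto[j] = maps_n[worst]
                    assignment[worst] = j
                    picked[worst] = 1.0
                    logger.warning("restart %d: empty cluster %d re-seeded", restart, j)
            gev = float((w2 * picked).sum() / denom)
            if gev - prev_gev < tol and n_iter > 1:
                break
            prev_gev = gev
            for j in range(k):
                members = maps[assignment == j]
                if len(members):
                    proto[j] = _dominant_eigenvector(members)
        corr = maps_n @ proto.T
        assignment = np.argmax(corr**2, axis=1)
        picked = np.take_along_axis(corr**2, assignment[:, None], axis=1)[:, 0]
        gev = float((w2 * picked).sum() / denom)
        if best is None or gev > best[0]:
            best = (gev, proto.copy(), assignment.copy(), n_iter)

    gev_total, proto, assignment, n_iter = best
    gev_total, per_class = compute_gev(peaks, PrototypeSet(maps=proto), assignment)
    order = np.argsort(-per_class)  # rank prototypes by explained variance
    proto = normalize_rows(proto[order])
    per_class = per_class[order]
    return PrototypeSet(
        maps=proto,
        gev_per_class=per_class,
        diagnostics={"gev_total": gev_total, "n_iter": n_iter, "k": k},
    )


def within_dispersion(peaks: PeakMaps | np.ndarray, prototypes: PrototypeSet) -> float:
    """Within-cluster dispersion W with dissimilarity ``1 - corr^2``.

    ``W = sum_c (1 / 2 n_c) * sum_{i,j in c} (1 - corr^2(x_i, x_j))``.
    """
    maps, _ = _as_maps_and_gfp(peaks)
    maps_n = normalize_rows(maps)
    assignment, _ = assign_peaks(maps, prototypes)
    w = 0.0
    for j in range(prototypes.k):
        members = maps_n[assignment == j]
        n_c = len(members)
        if n_c < 2:
            continue
        corr = members @ members.T
        w += (n_c**2 - float((corr**2).sum())) / (2.0 * n_c)
    return w


def cross_validation_criterion(peaks: PeakMaps | np.ndarray, prototypes: PrototypeSet) -> float:
    """Predictive residual-variance criterion, penalized for model order."""
    maps, _ = _as_maps_and_gfp(peaks)
    assignment, _ = assign_peaks(maps, prototypes)
    proto = normalize_rows(prototypes.maps)
    n, c = maps.shape
    if c - 1 - prototypes.k <= 0:
        return np.inf
    proj = np.take_along_axis(maps @ proto.T, assignment[:, None], axis=1)[:, 0]
    resid = float((maps**2).sum() - (proj**2).sum())
    sigma2 = resid / (n * (c - 1))
    return sigma2 * ((c - 1) / (c - 1 - prototypes.k)) ** 2


def scan_k(
    peaks: PeakMaps | np.ndarray,
    k_range: Iterable[int] = range(3, 9),
    n_restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
) -> list[PrototypeSet]:
    """Fit every ``k`` in ``k_range`` and attach CV / W / KL diagnostics.

    The Krzanowski-Lai index at ``k`` needs the dispersion at ``k - 1`` and
    ``k + 1``, so one extra model is fitted on each side of the requested
    range.  All criteria are reported, none is applied automatically.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    maps, _ = _as_maps_and_gfp(peaks)
    n, c = maps.shape
    ext = [k for k in range(max(1, ks[0] - 1), ks[-1] + 2) if k <= n]
    ss = np.random.SeedSequence(seed if seed is not None else 0).spawn(len(ext))
    fits: dict[int, PrototypeSet] = {}
    w: dict[int, float] = {}
    for child, k in zip(ss, ext):
        ps = modified_kmeans(peaks, k, n_restarts=n_restarts, max_iter=max_iter,
                             tol=tol, seed=int(child.generate_state(1)[0] % (2**31)))
        fits[k] = ps
        w[k] = within_dispersion(peaks, ps)

    m = c - 1  # effective dimensionality after average-referencing
    def diff(k: int) -> float:
        return (k - 1) ** (2.0 / m) * w[k - 1] - k ** (2.0 / m) * w[k]

    out = []
    for k in ks:
        ps = fits[k]
        kl = np.nan
        if k - 1 in w and k + 1 in w and k >= 2:
            d_next = diff(k + 1)
            kl = abs(diff(k)) / abs(d_next) if d_next != 0 else np.inf
        ps.diagnostics.update(
            cv=cross_validation_criterion(peaks, ps),
            w=w[k],
            kl=float(kl),
        )
        out.append(ps)
    return out


def label_prototypes(
    prototypes: PrototypeSet,
    templates: PrototypeSet | None = None,
) -> PrototypeSet:
    """Attach canonical class labels by optimal matching to template maps.

    Solves the one-to-one assignment maximizing the total absolute spatial
    correlation to the templates (exact, via the Hungarian algorithm) and
    returns a new set with maps reordered into template order (A, B, C, D
    for the built-in resting-state templates).
    """
    if templates is None:
        templates = canonical_templates(prototypes.n_channels)
    if prototypes.k != templates.k:
        raise ValueError(
            f"prototype count {prototypes.k} != template count {templates.k}"
        )
    score = np.abs(spatial_correlation(templates.maps, prototypes.maps))
    rows, cols = linear_sum_assignment(-score)
    order = cols[np.argsort(rows)]  # prototype index matched to template j
    return PrototypeSet(
        maps=prototypes.maps[order].copy(),
        labels=list(templates.labels),
        gev_per_class=None if prototypes.gev_per_class is None
        else prototypes.gev_per_class[order],
        diagnostics={
            **prototypes.diagnostics,
            "template_corr": score[np.arange(len(order)), order].tolist(),
        },
    )
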