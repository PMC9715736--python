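"""End-to-end orchestration: simulate (or load) -> preprocess -> segment ->
cluster -> back-fit -> features -> statistics.

A single :class:`PipelineConfig` drives every stage; all randomness flows
from its explicit integer seeds, so a run is deterministic (byte-identical
feature tables across reruns of the same config).  Every artifact is a
delimited text file in the run directory:

* ``prototypes.tsv``          group-level labeled prototype maps
* ``cohort_features.tsv``     one row per subject, 28 features + metadata
* ``ground_truth.tsv``        planted per-subject parameters (simulated runs)
* ``welch_tests.tsv``         Welch's t-test per feature
* ``scale_correlations.tsv``  Pearson + age-partial correlations (patients)
* ``anova.tsv``               two-factor ANOVA / ANCOVA for the top feature
* ``labels/<subject>.tsv``    run-length encoded microstate sequences
* ``report.txt``              human-readable summary

Group-level prototypes are fitted in two stages by default: a prototype
set per subject, then a second clustering of the pooled per-subject
prototypes; ``two_stage=False`` pools all peak maps directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .backfit import backfit
from .clustering import label_prototypes, modified_kmeans
from .containers import EEGRecording, PrototypeSet, SubjectMeta
from .features import FEATURE_COLUMNS, cohort_table, compute_features, features_to_row
from .preprocess import bandpass, common_average_reference, normalize_global
from .segmentation import compute_gfp, extract_peak_maps, find_gfp_peaks
from .stats import (
    ancova_group_effect,
    results_table,
    scale_correlation_table,
    two_factor_anova,
    welch_ttest_per_feature,
)
from .synthetic import CohortConfig, SyntheticConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class SimulateParams:
    enabled: bool = True
    n_per_group: int = 12
    duration: float = 60.0          # seconds per subject
    n_channels: int = 64
    fs: float = 250.0
    noise_sigma: float = 0.3
    dur_c_effect_ms: float = 25.0
    tp_cd_slope: float = 0.05
    dur_a_slope: float = -6.0


@dataclass
class PreprocessParams:
    normalize: bool = True
    bandpass: bool = False
    bandpass_low_hz: float = 1.0
    bandpass_high_hz: float = 45.0


@dataclass
class SegmentationParams:
    min_separation_ms: float = 10.0


@dataclass
class ClusteringParams:
    k: int = 4
    n_restarts: int = 20
    max_iter: int = 100
    tol: float = 1e-6
    two_stage: bool = True
    max_pooled_maps: int = 20000


@dataclass
class BackfitParams:
    min_duration_ms: float = 30.0


@dataclass
class PipelineConfig:
    seed: int
    simulate: SimulateParams = field(default_factory=SimulateParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    backfit: BackfitParams = field(default_factory=BackfitParams)
    input_dir: str | None = None    # read matrix EEG + metadata.tsv instead of simulating
    save_recordings: bool = False

    _SECTIONS = {
        "simulate": SimulateParams,
        "preprocess": PreprocessParams,
        "segmentation": SegmentationParams,
        "clustering": ClusteringParams,
        "backfit": BackfitParams,
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "seed" not in raw or raw["seed"] is None:
            raise ValueError("config must set an explicit integer seed")
        kwargs: dict = {"seed": int(raw.pop("seed"))}
        for name, typ in cls._SECTIONS.items():
            section = raw.pop(name, {}) or {}
            valid = {f.name for f in dataclasses.fields(typ)}
            unknown = set(section) - valid
            if unknown:
                raise ValueError(f"unknown keys in '{name}': {sorted(unknown)}")
            kwargs[name] = typ(**section)
        for key in ("input_dir", "save_recordings"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "input_dir": self.input_dir,
               "save_recordings": self.save_recordings}
        for name in self._SECTIONS:
            out[name] = dataclasses.asdict(getattr(self, name))
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    prototypes: PrototypeSet
    welch: pd.DataFrame
    correlations: pd.DataFrame
    anova: pd.DataFrame
    ground_truth: pd.DataFrame | None
    out_dir: Path | None
    generating_prototypes: PrototypeSet | None = None


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    logger.info("wrote %s (sha256 %s)", path.name, _checksum(path))


def _load_input_dir(input_dir: Path) -> tuple[list[EEGRecording], list[SubjectMeta]]:
    metas = msio.read_metadata(input_dir / "metadata.tsv")
    recs = []
    for m in metas:
        path = input_dir / f"{m.subject_id}.tsv"
        if not path.exists():
            edf = input_dir / f"{m.subject_id}.edf"
            if edf.exists():
                recs.append(msio.read_eeg(edf))
                continue
            raise FileNotFoundError(f"no EEG file for subject {m.subject_id}")
        recs.append(msio.read_eeg(path))
    return recs, metas


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute every stage and (optionally) write the run directory."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "labels").mkdir(exist_ok=True)
        config.to_yaml(out / "config_resolved.yaml")

    ground_truth = None
    gen_protos = None
    if config.input_dir:
        recordings, metas = _load_input_dir(Path(config.input_dir))
    elif config.simulate.enabled:
        sim = config.simulate
        base = SyntheticConfig(
            n_channels=sim.n_channels, fs=sim.fs, duration=sim.duration,
            noise_sigma=sim.noise_sigma, seed=config.seed,
        )
        cohort_cfg = CohortConfig(
            n_per_group=sim.n_per_group, dur_c_effect_ms=sim.dur_c_effect_ms,
            tp_cd_slope=sim.tp_cd_slope, dur_a_slope=sim.dur_a_slope,
            seed=config.seed + 1,
        )
        subjects, gen_protos = simulate_cohort(cohort_cfg, base)
        recordings = [s.recording for s in subjects]
        metas = [s.meta for s in subjects]
        gt_rows = []
        for s in subjects:
            row = {"subject_id": s.meta.subject_id, "group": s.meta.group}
            for c, name in enumerate("ABCD"):
                row[f"true_Dur_{name}"] = s.params["mean_durations_ms"][c]
            row["true_C-D"] = s.params["tp"][2, 3]
            gt_rows.append(row)
        ground_truth = pd.DataFrame(gt_rows)
        if out is not None:
            msio.write_prototypes(gen_protos, out / "generating_prototypes.tsv")
    else:
        raise ValueError("config requests neither simulation nor an input directory")

    # --- preprocess + segmentation, per subject ---------------------------
    gfps, peak_sets = [], []
    for i, rec in enumerate(recordings):
        rec = common_average_reference(rec)
        if config.preprocess.bandpass:
            rec = bandpass(rec, config.preprocess.bandpass_low_hz,
                           config.preprocess.bandpass_high_hz)
        if config.preprocess.normalize:
            rec = normalize_global(rec)
        recordings[i] = rec
        gfp = compute_gfp(rec)
        peaks = find_gfp_peaks(gfp, config.segmentation.min_separation_ms)
        gfps.append(gfp)
        peak_sets.append(extract_peak_maps(rec, peaks, gfp))
        if out is not None and config.save_recordings:
            msio.write_matrix(rec, out / f"{metas[i].subject_id}.tsv")
    logger.info("segmented %d subjects (%s peak maps)",
                len(recordings), sum(p.n_peaks for p in peak_sets))

    # --- group-level clustering ------------------------------------------
    cl = config.clustering
    rng = np.random.default_rng(config.seed + 1000)
    if cl.two_stage:
        per_subject = [
            modified_kmeans(p, cl.k, n_restarts=cl.n_restarts, max_iter=cl.max_iter,
                            tol=cl.tol, seed=config.seed + 2000 + i)
            for i, p in enumerate(peak_sets)
        ]
        pooled = np.vstack([ps.maps for ps in per_subject])
    else:
        pooled = np.vstack([p.maps for p in peak_sets])
        if len(pooled) > cl.max_pooled_maps:
            pooled = pooled[rng.choice(len(pooled), cl.max_pooled_maps, replace=False)]
    group_protos = modified_kmeans(pooled, cl.k, n_restarts=cl.n_restarts,
                                   max_iter=cl.max_iter, tol=cl.tol,
                                   seed=config.seed + 3000)
    group_protos = label_prototypes(group_protos)
    if out is not None:
        msio.write_prototypes(group_protos, out / "prototypes.tsv")

    # --- back-fitting + features -----------------------------------------
    rows = []
    for rec, gfp, meta in zip(recordings, gfps, metas):
        seq = backfit(rec, group_protos, min_duration_ms=config.backfit.min_duration_ms)
        feats = compute_features(seq, gfp=gfp, k=cl.k,
                                 class_labels=group_protos.labels)
        rows.append(features_to_row(feats, meta))
        if out is not None:
            msio.write_labels(seq, out / "labels" / f"{meta.subject_id}.tsv",
                              class_names=group_protos.labels)
    cohort = cohort_table(rows)

    # --- statistics -------------------------------------------------------
    feature_names = [c for c in FEATURE_COLUMNS if c in cohort.columns]
    welch = results_table(welch_ttest_per_feature(cohort, feature_names))
    has_scales = cohort["fma_total"].notna().sum() >= 4
    correlations = (
        scale_correlation_table(cohort, feature_names)
        if has_scales else pd.DataFrame()
    )
    top = welch.loc[welch["p"].idxmin(), "feature"]
    anova_results = [ancova_group_effect(cohort, top)]
    try:
        anova_results = two_factor_anova(cohort, top) + anova_results
    except ValueError as exc:
        # age can be fully confounded with group (as in age-mismatched cohorts)
        logger.warning("two-factor ANOVA skipped: %s", exc)
    anova = results_table(anova_results)

    if out is not None:
        _write(cohort, out / "cohort_features.tsv")
        _write(welch, out / "welch_tests.tsv")
        if len(correlations):
            _write(correlations, out / "scale_correlations.tsv")
        _write(anova, out / "anova.tsv")
        if ground_truth is not None:
            _write(ground_truth, out / "ground_truth.tsv")
        (out / "report.txt").write_text(summarize(cohort, welch, correlations, anova))

    return PipelineResult(cohort=cohort, prototypes=group_protos, welch=welch,
                          correlations=correlations, anova=anova,
                          ground_truth=ground_truth, out_dir=out,
                          generating_prototypes=gen_protos)


def summarize(cohort: pd.DataFrame, welch: pd.DataFrame,
              correlations: pd.DataFrame, anova: pd.DataFrame) -> str:
    """Human-readable run summary."""
    lines = [
        "Microstate pipeline summary",
        "===========================",
        f"subjects: {len(cohort)} "
        f"({(cohort['group'] == 'patient').sum()} patient / "
        f"{(cohort['group'] == 'healthy').sum()} healthy)",
        "",
        "Group differences (Welch's t, two-tailed, alpha = 0.05):",
    ]
    sig = welch[welch["p"] < 0.05].sort_values("p")
    if len(sig):
        for _, r in sig.iterrows():
            lines.append(f"  {r['feature']}: t = {r['statistic']:.3f}, "
                         f"df = {r['df']:.1f}, p = {r['p']:.4f}")
    else:
        lines.append("  none significant")
    if len(correlations):
        lines += ["", "Scale correlations within the patient group (|p| < 0.05):"]
        sig = correlations[correlations["p"] < 0.05].sort_values("p")
        for _, r in sig.iterrows():
            lines.append(
                f"  {r['feature']} ~ {r['scale']}: r = {r['r']:.4f} "
                f"(p = {r['p']:.4f}); age-partial r = {r['partial_r']:.4f} "
                f"(p = {r['partial_p']:.4f})"
            )
        if not len(sig):
            lines.append("  none significant")
    lines += ["", "Two-factor ANOVA / ANCOVA on the top group-difference feature:"]
    for _, r in anova.iterrows():
        lines.append(f"  {r['feature']}: F = {r['statistic']:.3f}, p = {r['p']:.4f}")
    return "\n".join(lines) + "\n"
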