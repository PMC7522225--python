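"""Desk-scale orchestration: cohort in, study-style tables out.

Runs the full analysis for each (pairwise comparison, retinal layer) pair:
pixel extraction inside the ETDRS grid -> pooled micrometre-to-[0,1]
transform -> per-subject kernel densities -> square-root-transform geometry
-> per-group Karcher means and tail-mass summaries -> leave-one-out
classification with density features and with the five-number-summary
baseline -> permutation test on the geodesic distance between group means.

Leakage policy: the pooled domain transform is recomputed per LOOCV fold
from the training subjects only.  Because the min-max transform changes
only for folds that hold out the pooled extremum, at most three distinct
transforms occur per comparison; densities are cached per transform.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .classification import (
    ClassifierConfig,
    ClassificationReport,
    _assemble_report,
    _fold_probability,
    loocv_evaluate,
    summary_feature_baseline,
)
from .density_estimation import (
    DomainTransform,
    estimate_pdf,
    pooled_domain_transform,
    tail_mass_above,
)
from .image_extraction import PixelSample, build_etdrs_mask, extract_pixels, orient_map
from .permutation_test import PermTestResult, perm_test
from .sphere_geometry import (
    DensityFunction,
    KarcherMeanResult,
    karcher_mean,
    srt,
    trapezoid_weights,
)
from .tangent_pca import fit as fit_pca_at_mean, principal_path
from .synthetic_data import SyntheticSubject

__all__ = [
    "DEFAULT_COMPARISONS",
    "AnalysisConfig",
    "PairwiseResult",
    "config_hash",
    "cohort_pixel_samples",
    "run_pairwise",
    "analyze_samples",
    "analyze_pixel_table",
    "results_tables",
    "write_report_csv",
]

DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("NoDR", "NPDR"),
    ("controls", "NPDR"),
    ("controls", "NoDR"),
)


@dataclass
class AnalysisConfig:
    """All analysis knobs; defaults mirror the study settings."""

    layers: list[str] | None = None  # None: every layer present in the data
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_COMPARISONS]
    )
    grid_size: int = 512
    bandwidth: float | None = None  # None: Silverman rule per subject
    variance_threshold: float = 0.9999
    ci_overall_alpha: float = 0.05
    ci_comparisons: int = 3
    threshold: float | str = 0.5
    n_perm: int = 10_000
    seed: int = 0
    pca_scope: str = "per_fold"
    transform_scope: str = "per_fold"  # or "global"
    p_direction: str = "conventional"
    center_tangent: bool = True
    ridge: float = 1e-6
    karcher_tol: float = 1e-6
    karcher_step: float = 0.5
    karcher_max_iter: int = 100

    def classifier(self) -> ClassifierConfig:
        return ClassifierConfig(
            variance_threshold=self.variance_threshold,
            ci_overall_alpha=self.ci_overall_alpha,
            ci_comparisons=self.ci_comparisons,
            threshold=self.threshold,
            pca_scope=self.pca_scope,
            center_tangent=self.center_tangent,
            ridge=self.ridge,
            karcher_tol=self.karcher_tol,
            karcher_step=self.karcher_step,
            karcher_max_iter=self.karcher_max_iter,
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        if "comparisons" in d:
            d["comparisons"] = [tuple(c) for c in d["comparisons"]]
        if "layers" in d and d["layers"] is not None:
            d["layers"] = list(d["layers"])
        return cls(**d)


def config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _pair_seed(base_seed: int, layer: str, comparison: tuple[str, str]) -> int:
    tag = f"{layer}|{comparison[0]}|{comparison[1]}"
    return int((base_seed ^ zlib.crc32(tag.encode())) % (2**31))


@dataclass
class PairwiseResult:
    comparison: tuple[str, str]
    layer: str
    subject_ids: list[str]
    y: np.ndarray
    transform: DomainTransform
    density_report: ClassificationReport
    summary_report: ClassificationReport
    perm_result: PermTestResult | None
    karcher_means: dict[str, KarcherMeanResult]
    tail_mass_above_50: dict[str, float]
    #: per group: densities at -2..+2 score SDs along the group's first
    #: principal direction (empty list when a group has < 2 subjects)
    principal_paths: dict[str, list[DensityFunction]] = field(default_factory=dict)
    principal_path_sd_multiples: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)


def cohort_pixel_samples(
    cohort: Sequence[SyntheticSubject], layers: Sequence[str] | None = None
) -> list[dict[str, Any]]:
    """Extract every subject's ETDRS pixel sample for each requested layer.

    Applies laterality orientation, places the ETDRS grid at the recorded
    fovea centre, and pools all non-missing in-disc pixels.
    """
    records: list[dict[str, Any]] = []
    for subj in cohort:
        wanted = layers if layers is not None else list(subj.maps)
        for layer in wanted:
            if layer not in subj.maps:
                raise ValueError(f"subject {subj.subject_id} has no map for layer {layer!r}")
            tmap = orient_map(subj.maps[layer])
            mask = build_etdrs_mask(tmap.shape, tmap.center, tmap.pixel_spacing)
            sample = extract_pixels(tmap, mask, subject_id=subj.subject_id, layer=layer)
            if len(sample) == 0:
                raise ValueError(
                    f"subject {subj.subject_id}, layer {layer}: no usable ETDRS pixels"
                )
            records.append(
                {
                    "subject_id": subj.subject_id,
                    "group": subj.group,
                    "laterality": subj.laterality,
                    "layer": layer,
                    "sample": sample,
                }
            )
    return records


def _fold_transform_groups(
    samples: Sequence[PixelSample],
) -> dict[tuple[float, float], list[int]]:
    """Map each fold to the pooled (min, max) of its training subjects."""
    mins = np.array([float(s.values.min()) for s in samples])
    maxs = np.array([float(s.values.max()) for s in samples])
    n = mins.size
    order_min = np.argsort(mins)
    order_max = np.argsort(maxs)
    gmin, gmax = mins[order_min[0]], maxs[order_max[-1]]
    second_min = mins[order_min[1]] if n > 1 else gmin
    second_max = maxs[order_max[-2]] if n > 1 else gmax
    unique_min = n > 1 and mins[order_min[1]] > gmin
    unique_max = n > 1 and maxs[order_max[-2]] < gmax
    groups: dict[tuple[float, float], list[int]] = {}
    for i in range(n):
        tmin = second_min if (unique_min and i == order_min[0]) else gmin
        tmax = second_max if (unique_max and i == order_max[-1]) else gmax
        groups.setdefault((tmin, tmax), []).append(i)
    return groups


def _transform_from_range(tmin: float, tmax: float, pad_fraction: float = 0.01) -> DomainTransform:
    rng = tmax - tmin
    pad = pad_fraction * rng if rng > 0 else 1.0
    return DomainTransform(a=tmin - pad, b=rng + 2.0 * pad)


def _loocv_density_fold_transforms(
    samples: Sequence[PixelSample],
    y: np.ndarray,
    config: AnalysisConfig,
) -> ClassificationReport:
    """Density-feature LOOCV with the pooled transform refitted per fold."""
    cfg = config.classifier()
    n = len(samples)
    p = np.empty(n)
    from .sphere_geometry import _karcher_stack  # local import: private helper

    for (tmin, tmax), fold_idx in _fold_transform_groups(samples).items():
        T = _transform_from_range(tmin, tmax)
        dens = [
            estimate_pdf(s, T, grid_size=config.grid_size, bandwidth=config.bandwidth)
            for s in samples
        ]
        grid = dens[0].grid
        H = np.stack([np.sqrt(d.values) for d in dens])
        wq = trapezoid_weights(grid.size)
        W = np.zeros((len(fold_idx), n))
        for row, i in enumerate(fold_idx):
            W[row] = 1.0 / (n - 1)
            W[row, i] = 0.0
        mus, _, _, _ = _karcher_stack(
            H, W, wq, tol=cfg.karcher_tol, step=cfg.karcher_step, max_iter=cfg.karcher_max_iter
        )
        for row, i in enumerate(fold_idx):
            p[i] = _fold_probability(H, grid, wq, y, i, mus[row], cfg)
    return _assemble_report(p, y, cfg, "density-based")


def _run_pairwise_samples(
    records: list[dict[str, Any]],
    layer: str,
    comparison: tuple[str, str],
    config: AnalysisConfig,
) -> PairwiseResult:
    rows = [r for r in records if r["layer"] == layer and r["group"] in comparison]
    for g in comparison:
        if not any(r["group"] == g for r in rows):
            raise ValueError(f"comparison {comparison}: no subjects in group {g!r}")
    samples = [r["sample"] for r in rows]
    subject_ids = [r["subject_id"] for r in rows]
    y = np.array([int(r["group"] == comparison[1]) for r in rows])

    transform = pooled_domain_transform(samples)
    densities = [
        estimate_pdf(s, transform, grid_size=config.grid_size, bandwidth=config.bandwidth)
        for s in samples
    ]
    hs = [srt(f) for f in densities]

    means: dict[str, KarcherMeanResult] = {}
    tails: dict[str, float] = {}
    paths: dict[str, list[DensityFunction]] = {}
    sd_multiples = (-2.0, -1.0, 0.0, 1.0, 2.0)
    for label, g in zip((0, 1), comparison):
        sub = [h for h, yi in zip(hs, y) if yi == label]
        res = karcher_mean(
            sub, tol=config.karcher_tol, max_iter=config.karcher_max_iter, step=config.karcher_step
        )
        means[g] = res
        tails[g] = tail_mass_above(res.mean_density, 50.0)
        if len(sub) >= 2:
            group_pca = fit_pca_at_mean(
                res.mean, sub, config.variance_threshold, center=config.center_tangent
            )
            paths[g] = (
                principal_path(group_pca, 1, sd_multiples) if group_pca.r >= 1 else []
            )
        else:
            paths[g] = []

    perm = None
    if config.n_perm > 0:
        perm = perm_test(
            hs,
            y,
            n_perm=config.n_perm,
            seed=_pair_seed(config.seed, layer, comparison),
            direction=config.p_direction,
            k_comparisons=config.ci_comparisons,
            karcher_tol=config.karcher_tol,
            karcher_step=config.karcher_step,
            karcher_max_iter=config.karcher_max_iter,
        )

    if config.transform_scope == "per_fold":
        density_report = _loocv_density_fold_transforms(samples, y, config)
    else:
        density_report = loocv_evaluate(densities, y, config.classifier())
    summary_report = loocv_evaluate(
        None, y, config.classifier(), features=summary_feature_baseline(samples)
    )
    return PairwiseResult(
        comparison=comparison,
        layer=layer,
        subject_ids=subject_ids,
        y=y,
        transform=transform,
        density_report=density_report,
        summary_report=summary_report,
        perm_result=perm,
        karcher_means=means,
        tail_mass_above_50=tails,
        principal_paths=paths,
        principal_path_sd_multiples=sd_multiples,
    )


def run_pairwise(
    cohort: Sequence[SyntheticSubject],
    layer: str,
    comparison: tuple[str, str],
    config: AnalysisConfig | None = None,
) -> PairwiseResult:
    """Full pipeline for one layer and one pairwise group comparison."""
    config = config or AnalysisConfig()
    subset = [s for s in cohort if s.group in comparison]
    records = cohort_pixel_samples(subset, layers=[layer])
    return _run_pairwise_samples(records, layer, comparison, config)


def analyze_samples(
    records: list[dict[str, Any]], config: AnalysisConfig | None = None
) -> dict[tuple[str, str, str], PairwiseResult]:
    """Run every configured (comparison, layer) pair on extracted samples."""
    config = config or AnalysisConfig()
    layers = config.layers or sorted({r["layer"] for r in records})
    out: dict[tuple[str, str, str], PairwiseResult] = {}
    for comparison in config.comparisons:
        for layer in layers:
            res = _run_pairwise_samples(records, layer, tuple(comparison), config)
            out[(comparison[0], comparison[1], layer)] = res
    return out


def analyze_pixel_table(
    df: pd.DataFrame, config: AnalysisConfig | None = None
) -> dict[tuple[str, str, str], PairwiseResult]:
    """Analyze a long pixel table (subject_id, group, layer, value)."""
    required = {"subject_id", "group", "layer", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"pixel table must have columns {sorted(required)}")
    records = []
    for (sid, group, layer), sub in df.groupby(
        ["subject_id", "group", "layer"], sort=True
    ):
        records.append(
            {
                "subject_id": str(sid),
                "group": str(group),
                "laterality": str(sub["laterality"].iloc[0]) if "laterality" in sub else "right",
                "layer": str(layer),
                "sample": PixelSample(
                    values=sub["value"].to_numpy(float), subject_id=str(sid), layer=str(layer)
                ),
            }
        )
    return analyze_samples(records, config)


def results_tables(
    results: dict[tuple[str, str, str], PairwiseResult]
) -> dict[str, pd.DataFrame]:
    """Study-style report tables from a batch of pairwise results."""
    dens, summ, perm, tails = [], [], [], []
    for (g0, g1, layer), res in results.items():
        comp = f"{g0} vs {g1}"
        for tag, rep in (("density-based", res.density_report), ("five-number-summary", res.summary_report)):
            row = {
                "comparison": comp,
                "layer": layer,
                "feature_set": tag,
                "auc": rep.auc,
                "ci_low": rep.ci_low,
                "ci_high": rep.ci_high,
                "ci_level": rep.ci_level,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "brier": rep.brier,
            }
            (dens if tag == "density-based" else summ).append(row)
        if res.perm_result is not None:
            perm.append(
                {
                    "comparison": comp,
                    "layer": layer,
                    "d0": res.perm_result.d0,
                    "p_raw": res.perm_result.p_raw,
                    "p_adjusted": res.perm_result.p_adjusted,
                    "n_permutations": res.perm_result.n_permutations,
                }
            )
        for g, tm in res.tail_mass_above_50.items():
            tails.append(
                {"comparison": comp, "layer": layer, "group": g, "tail_mass_above_50": tm}
            )
    return {
        "density_reports": pd.DataFrame(dens),
        "summary_reports": pd.DataFrame(summ),
        "permutation_tests": pd.DataFrame(perm),
        "tail_mass": pd.DataFrame(tails),
    }


def write_report_csv(df: pd.DataFrame, path: str | Path, config: AnalysisConfig) -> Path:
    """CSV with a config-hash header so reruns are verifiably identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash(config)} seed={config.seed}\n")
        df.to_csv(fh, index=False)
    return path
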