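"""Challenge evaluation protocol.

Target registration error (TRE) is the Euclidean distance between the
ground-truth intraoperative position of a validation target and its
registered estimate.  Summaries are stratified by surface-data extent and by
anatomical segment, sensitivity to digitization noise is expressed through
the noise efficiency E_N = A_N / mean-TRE(noisy) and noise degradation
D_N = (mean-TRE(noisy) - mean-TRE(clean)) / A_N, displacement fields are
checked for biomechanical consistency through per-element Green-strain norms
and Jacobian determinants, and methods are compared through per-target TRE
correlation and paired nonparametric tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fields import (
    DisplacementField,
    element_displacement_gradients,
    green_strain_norm,
    jacobian_determinant,
)
from .geometry import InvalidInputError, TetVolumeMesh


@dataclass
class TargetSet:
    """Paired ground-truth and estimated target coordinates (mm)."""

    ground_truth: np.ndarray
    estimated: np.ndarray
    segments: np.ndarray | None = None

    def __post_init__(self):
        self.ground_truth = np.asarray(self.ground_truth, dtype=float)
        self.estimated = np.asarray(self.estimated, dtype=float)
        if self.ground_truth.shape != self.estimated.shape:
            raise InvalidInputError("ground-truth / estimate count mismatch")
        if not (
            np.all(np.isfinite(self.ground_truth))
            and np.all(np.isfinite(self.estimated))
        ):
            raise InvalidInputError("target coordinates must be finite")
        if self.segments is not None and len(self.segments) != len(self.ground_truth):
            raise InvalidInputError("one segment label per target required")


@dataclass
class TreSummary:
    per_target: np.ndarray
    mean: float
    std: float
    median: float


def compute_tre(targets: TargetSet) -> TreSummary:
    """Per-target TRE_i = ||x_GT,i - x_est,i||_2 with mean/std/median."""
    tre = np.linalg.norm(targets.ground_truth - targets.estimated, axis=1)
    return TreSummary(tre, float(tre.mean()), float(tre.std(ddof=0)),
                      float(np.median(tre)))


def noise_metrics(
    mean_tre_noisy: float, mean_tre_clean: float, amplitude: float
):
    """Noise efficiency and degradation of a registration method.

    E_N = A_N / mean-TRE(noisy); D_N = (mean-TRE(noisy) - mean-TRE(clean)) / A_N.
    E_N is ``nan`` when the noisy mean TRE is zero.
    """
    if amplitude <= 0:
        raise InvalidInputError("noise amplitude must be positive")
    if mean_tre_noisy < 0 or mean_tre_clean < 0:
        raise InvalidInputError("mean TREs must be non-negative")
    efficiency = amplitude / mean_tre_noisy if mean_tre_noisy > 0 else float("nan")
    degradation = (mean_tre_noisy - mean_tre_clean) / amplitude
    return efficiency, degradation


DEFAULT_EXTENT_EDGES = (20.0, 28.0, 36.0, 44.0)


def stratify_by_extent(
    values: np.ndarray,
    extents: np.ndarray,
    edges: tuple = DEFAULT_EXTENT_EDGES,
) -> pd.DataFrame:
    """Bin per-instance summaries by surface-coverage extent.

    Bins are half-open on the left, ``[e_k, e_{k+1})``, with the final bin
    closed; out-of-range instances are reported in an ``outside`` row.
    """
    values = np.asarray(values, dtype=float)
    extents = np.asarray(extents, dtype=float)
    if values.shape != extents.shape:
        raise InvalidInputError("one extent per instance required")
    rows = []
    assigned = np.zeros(len(values), dtype=bool)
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        if k == len(edges) - 2:
            mask = (extents >= lo) & (extents <= hi)
        else:
            mask = (extents >= lo) & (extents < hi)
        mask &= ~assigned
        assigned |= mask
        sel = values[mask]
        rows.append(
            {
                "bin": f"[{lo:g}, {hi:g}{']' if k == len(edges) - 2 else ')'}",
                "count": int(mask.sum()),
                "mean": float(sel.mean()) if len(sel) else float("nan"),
                "std": float(sel.std(ddof=0)) if len(sel) else float("nan"),
                "median": float(np.median(sel)) if len(sel) else float("nan"),
            }
        )
    out = ~assigned
    rows.append(
        {
            "bin": "outside",
            "count": int(out.sum()),
            "mean": float(values[out].mean()) if out.any() else float("nan"),
            "std": float(values[out].std(ddof=0)) if out.any() else float("nan"),
            "median": float(np.median(values[out])) if out.any() else float("nan"),
        }
    )
    return pd.DataFrame(rows).set_index("bin")


def stratify_by_segment(
    per_target_tre: np.ndarray,
    segments: np.ndarray,
    min_count: int = 5,
) -> pd.DataFrame:
    """Per-segment TRE summaries; under-populated segments are flagged
    ``excluded`` (mirroring the exclusion of segments with too few
    validation targets)."""
    tre = np.asarray(per_target_tre, dtype=float)
    segments = np.asarray(segments)
    if tre.shape[0] != segments.shape[0]:
        raise InvalidInputError("one segment label per target required")
    rows = []
    for lab in np.unique(segments):
        sel = tre[segments == lab]
        rows.append(
            {
                "segment": lab,
                "count": len(sel),
                "mean": float(sel.mean()),
                "std": float(sel.std(ddof=0)),
                "median": float(np.median(sel)),
                "excluded": len(sel) < min_count,
            }
        )
    return pd.DataFrame(rows).set_index("segment")


def field_consistency(
    mesh: TetVolumeMesh, fields: list[DisplacementField]
):
    """Mean per-element strain norm and Jacobian determinant across fields.

    Each field is differentiated and measured separately, then the
    per-element measures are averaged across fields (mean of per-field
    values, not the measure of the mean field).
    """
    if not fields:
        raise InvalidInputError("at least one field required")
    strain_acc = np.zeros(mesh.n_tets)
    jac_acc = np.zeros(mesh.n_tets)
    for f in fields:
        grads = element_displacement_gradients(mesh, f)
        strain_acc += green_strain_norm(grads)
        jac_acc += jacobian_determinant(grads)
    n = len(fields)
    return strain_acc / n, jac_acc / n


def tre_correlation(per_target_tre_by_method: dict) -> pd.DataFrame:
    """Pearson correlation matrix of per-target TRE across methods.

    Columns must share the target indexing.  A zero-variance method yields
    ``nan`` entries (flagged undefined).
    """
    names = list(per_target_tre_by_method)
    mat = np.column_stack([np.asarray(per_target_tre_by_method[n], float)
                           for n in names])
    if mat.ndim != 2 or len(set(map(len, per_target_tre_by_method.values()))) != 1:
        raise InvalidInputError("methods must share target indexing")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=names, columns=names)


def fuse_fields(fields: list[DisplacementField]) -> DisplacementField:
    """Node-wise arithmetic mean of displacement fields (decision fusion)."""
    if not fields:
        raise InvalidInputError("at least one field required")
    n = len(fields[0])
    if any(len(f) != n for f in fields):
        raise InvalidInputError("fields must share the node count")
    return DisplacementField(np.mean([f.values for f in fields], axis=0))


@dataclass
class MethodComparison:
    friedman_statistic: float
    friedman_p: float
    pairwise: pd.DataFrame
    alpha: float = 0.05

    @property
    def any_significant(self) -> bool:
        return bool((self.pairwise["p_adjusted"] < self.alpha).any())


def compare_methods(
    per_instance_by_method: dict, alpha: float = 0.05
) -> MethodComparison:
    """Friedman test across methods plus Bonferroni-adjusted pairwise
    Wilcoxon signed-rank comparisons on paired per-instance summaries."""
    names = list(per_instance_by_method)
    if len(names) < 2:
        raise InvalidInputError("need at least two methods to compare")
    cols = [np.asarray(per_instance_by_method[n], float) for n in names]
    n_inst = len(cols[0])
    if any(len(c) != n_inst for c in cols):
        raise InvalidInputError("methods must be paired across instances")
    if n_inst < 3:
        raise InvalidInputError("too few instances for the Friedman test")
    stacked = np.column_stack(cols)
    if np.allclose(stacked.var(axis=1), 0.0):
        stat, p = 0.0, 1.0
    elif len(cols) == 2:
        # Friedman needs >= 3 groups; for two paired groups the Wilcoxon
        # signed-rank test serves as the omnibus comparison
        stat, p = stats.wilcoxon(cols[0], cols[1])
    else:
        stat, p = stats.friedmanchisquare(*cols)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = cols[i] - cols[j]
            if np.allclose(diff, 0.0):
                w, pw = 0.0, 1.0
            else:
                w, pw = stats.wilcoxon(cols[i], cols[j])
            rows.append(
                {
                    "method_a": names[i],
                    "method_b": names[j],
                    "statistic": float(w),
                    "p_raw": float(pw),
                    "p_adjusted": float(min(1.0, m * pw)),
                }
            )
    return MethodComparison(float(stat), float(p), pd.DataFrame(rows), alpha)


def noise_group_tests(noisy: np.ndarray, clean: np.ndarray) -> dict:
    """Location (Wilcoxon rank-sum) and spread (Brown-Forsythe) tests
    between noisy and clean per-instance summaries, plus a two-sample
    Kolmogorov-Smirnov distribution test."""
    noisy = np.asarray(noisy, float)
    clean = np.asarray(clean, float)
    out = {}
    if len(noisy) < 2 or len(clean) < 2:
        return {"skipped": True}
    rs = stats.ranksums(noisy, clean)
    bf = stats.levene(noisy, clean, center="median")
    ks = stats.ks_2samp(noisy, clean)
    out.update(
        ranksum_statistic=float(rs.statistic), ranksum_p=float(rs.pvalue),
        brown_forsythe_statistic=float(bf.statistic),
        brown_forsythe_p=float(bf.pvalue),
        ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue),
        skipped=False,
    )
    return out
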