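"""ROC/AUC computation and experiment runners.

Classification quality is reported exclusively as the area under the ROC
curve: the probability that a randomly chosen cancer-positive unit scores
higher than a randomly chosen negative one, with ties credited one half.
With test sets of 12-25 units the ROC curve is strongly discretized and any
single sensitivity/specificity pair would be misleading, so thresholded
metrics are not reported by default.

The runners reproduce the study's two experiment shapes: a comparison of the
best single- and multi-feature representations per mode and wavelength
restriction, and a sparse-optode-grid ablation that re-runs the pipeline on
channel subsets emulating smaller instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._errors import UndefinedAUCError, ValidationError
from .core import Cohort, GridGeometry, subset_cohort
from .representations import RepresentationSpec


@dataclass(frozen=True)
class ROCResult:
    """An ROC curve with its area and class counts."""

    points: tuple[tuple[float, float], ...]  # (FPR, TPR) from (0,0) to (1,1)
    auc: float
    n_pos: int
    n_neg: int


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve and AUC from decision scores and binary labels.

    The curve sweeps thresholds over the distinct score values in descending
    order; the AUC is the Mann-Whitney pair statistic — the fraction of
    (positive, negative) pairs ranked correctly, ties counting one half —
    which equals the trapezoidal area under the curve.

    Raises
    ------
    UndefinedAUCError
        If only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError(
            f"scores and labels must be equal-length vectors, got {scores.shape} and {labels.shape}"
        )
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(f"AUC undefined with n_pos={n_pos}, n_neg={n_neg}")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # cumulative counts at each distinct-score threshold
    is_last_of_tie = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp = np.cumsum(sorted_labels == 1)[is_last_of_tie]
    fp = np.cumsum(sorted_labels == 0)[is_last_of_tie]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    points = tuple((float(x), float(y)) for x, y in zip(fpr, tpr))
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(points=points, auc=auc, n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# Experiment runners
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonRow:
    """One row of the representation-comparison report."""

    mode: str
    scope: str  # "single" or "concatenated"
    wavelengths: tuple[int, ...]
    spec: RepresentationSpec
    C: float
    validation_auc: float
    test_auc: float

    def label(self) -> str:
        return self.spec.label()


@dataclass(frozen=True)
class AblationRow:
    grid_size_label: str
    grid_name: str
    mode: str
    auc: float


@dataclass(frozen=True)
class AblationReport:
    rows: tuple[AblationRow, ...]

    def summaries(self) -> list[dict]:
        """Median/min/max test AUC per (grid size, mode)."""
        out = []
        keys = sorted({(r.grid_size_label, r.mode) for r in self.rows})
        for size_label, mode in keys:
            aucs = [r.auc for r in self.rows if r.grid_size_label == size_label and r.mode == mode]
            out.append({
                "grid_size_label": size_label,
                "mode": mode,
                "n_grids": len(aucs),
                "median_auc": float(np.median(aucs)),
                "min_auc": float(min(aucs)),
                "max_auc": float(max(aucs)),
            })
        return out


def run_comparison(cohort: Cohort, modes: Sequence[str] = ("unilateral", "bilateral"),
                   wavelength_restrictions: Sequence[tuple[int, ...]] = ((760,), (830,), (760, 830)),
                   plan_seed: int = 0, C_grid: Sequence[float] | None = None,
                   n_splits: int = 20, test_frac: float = 0.2, val_frac: float = 0.2,
                   ) -> list[ComparisonRow]:
    """Best single- and multi-feature representation per mode and wavelength set.

    For each mode, one split plan (derived from ``plan_seed``) is shared
    across all wavelength restrictions so that differences between rows
    reflect the representations, not split noise.  Single-feature candidates
    use one wavelength and one normalization; concatenated candidates are the
    full enumeration under the restriction.
    """
    from .model_selection import final_evaluate, make_split_plan, select_model
    from .representations import enumerate_specs, single_feature_specs

    rows = []
    for mode in modes:
        plan = make_split_plan(cohort, mode=mode, test_frac=test_frac,
                               val_frac=val_frac, n_splits=n_splits, seed=plan_seed)
        for wls in wavelength_restrictions:
            candidates = {
                "single": [s for s in single_feature_specs()
                           if set(s.wavelengths) <= set(wls)],
                "concatenated": [s for s in enumerate_specs() if s.wavelengths == tuple(sorted(wls))],
            }
            for scope, specs in candidates.items():
                result = select_model(cohort, specs, plan=plan, mode=mode, C_grid=C_grid)
                roc = final_evaluate(cohort, result, plan=plan, mode=mode)
                rows.append(ComparisonRow(
                    mode=mode, scope=scope, wavelengths=tuple(sorted(wls)),
                    spec=result.best_spec, C=result.best_C,
                    validation_auc=result.validation_auc_mean, test_auc=roc.auc,
                ))
    return rows


def run_sparse_ablation(cohort: Cohort, grids: Sequence[GridGeometry],
                        spec_uni: RepresentationSpec, spec_bi: RepresentationSpec,
                        plan_seed: int = 0, C_grid: Sequence[float] | None = None,
                        n_splits: int = 20, test_frac: float = 0.2, val_frac: float = 0.2,
                        ) -> AblationReport:
    """Re-run selection and evaluation on channel subsets emulating sparse arrays.

    For every grid geometry, all blocks are restricted to the kept channels and
    the pipeline is re-run (hyperparameter re-selection included) with the
    same plan seed, once per mode with the given representation spec.
    """
    from .model_selection import final_evaluate, make_split_plan, select_model

    rows = []
    for grid in grids:
        sub = subset_cohort(cohort, grid)
        for mode, spec in (("unilateral", spec_uni), ("bilateral", spec_bi)):
            plan = make_split_plan(sub, mode=mode, test_frac=test_frac,
                                   val_frac=val_frac, n_splits=n_splits, seed=plan_seed)
            result = select_model(sub, [spec], plan=plan, mode=mode, C_grid=C_grid)
            roc = final_evaluate(sub, result, plan=plan, mode=mode)
            rows.append(AblationRow(
                grid_size_label=grid.size_label, grid_name=grid.name,
                mode=mode, auc=roc.auc,
            ))
    return AblationReport(rows=tuple(rows))
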