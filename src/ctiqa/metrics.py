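"""Correlation-based evaluation protocol for quality-score regression.

A trained scorer is judged by how well its predictions track the reference
(radiologist-style) scores: Pearson's linear correlation r, Spearman's rank
correlation rho, Kendall's tau-b (tie-corrected), their absolute-value sum

    s = |r| + |rho| + |tau|        (bounded by 3)

as the headline aggregate, plus the coefficient of determination R^2,
range-wise grouping of the 0-4 scale into unit bins with per-group accuracy,
and per-scan averaging of slice scores.  Correlations are undefined on
constant vectors; these raise :class:`UndefinedCorrelationError` rather than
silently returning zero, since a silent zero would corrupt s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScorePairs",
    "EvalReport",
    "UndefinedCorrelationError",
    "pearson_r",
    "spearman_rho",
    "kendall_tau",
    "overall_s",
    "r_squared",
    "range_wise_eval",
    "scan_score",
    "export_residuals",
    "evaluate_pairs",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation has no defined value (constant input)."""


@dataclass
class ScorePairs:
    """Reference and predicted scores, element-aligned."""

    reference: np.ndarray
    predicted: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        self.predicted = np.asarray(self.predicted, dtype=np.float64)
        if self.reference.shape != self.predicted.shape:
            raise ValueError(
                f"length mismatch: {self.reference.shape} vs {self.predicted.shape}"
            )
        if self.ids is None:
            self.ids = [str(i) for i in range(len(self.reference))]
        elif len(self.ids) != len(self.reference):
            raise ValueError("ids length does not match score vectors")

    def __len__(self) -> int:
        return len(self.reference)


def _check(pairs: ScorePairs, need_nonconstant: str = "either") -> None:
    if len(pairs) < 2:
        raise ValueError("correlation requires at least two score pairs")
    ref_const = np.ptp(pairs.reference) == 0
    pred_const = np.ptp(pairs.predicted) == 0
    if need_nonconstant == "either" and (ref_const or pred_const):
        raise UndefinedCorrelationError(
            "correlation undefined: constant score vector"
        )
    if need_nonconstant == "reference" and ref_const:
        raise UndefinedCorrelationError("undefined: constant reference scores")


def pearson_r(pairs: ScorePairs) -> float:
    """Pearson product-moment correlation between reference and prediction."""
    _check(pairs)
    return float(stats.pearsonr(pairs.reference, pairs.predicted).statistic)


def spearman_rho(pairs: ScorePairs) -> float:
    """Spearman rank correlation.

    Tie-free data follows the classical 1 - 6*sum(d^2)/(n(n^2-1)) rank-
    difference form exactly; ties are handled by average ranks (equivalent to
    Pearson on midranks), the standard extension of the tie-free formula.
    """
    _check(pairs)
    return float(stats.spearmanr(pairs.reference, pairs.predicted).statistic)


def kendall_tau(pairs: ScorePairs) -> float:
    """Kendall tau-b: (P - Q) / sqrt((P+Q+T_ref)(P+Q+T_pred)) where P/Q count
    concordant/discordant pairs and the T terms count pairs tied on exactly
    one of the two vectors; pairs tied on both are excluded throughout."""
    _check(pairs)
    return float(
        stats.kendalltau(pairs.reference, pairs.predicted, variant="b").statistic
    )


def overall_s(r: float, rho: float, tau: float) -> float:
    """Aggregate score s = |r| + |rho| + |tau|, bounded by [0, 3]."""
    for name, v in (("r", r), ("rho", rho), ("tau", tau)):
        if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
            raise ValueError(f"{name}={v} outside [-1, 1]")
    return abs(r) + abs(rho) + abs(tau)


def r_squared(pairs: ScorePairs) -> float:
    """Coefficient of determination with the reference as ground truth."""
    if len(pairs) < 2:
        raise ValueError("R^2 requires at least two score pairs")
    _check(pairs, need_nonconstant="reference")
    ss_res = float(np.sum((pairs.reference - pairs.predicted) ** 2))
    ss_tot = float(np.sum((pairs.reference - pairs.reference.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


_GROUPS = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0))


def _group_of(score: float) -> int:
    """Unit-bin index on the 0-4 scale: [0,1), [1,2), [2,3), [3,4]."""
    if score >= 3.0:
        return 3
    return int(score)


def range_wise_eval(pairs: ScorePairs) -> dict:
    """Group test pairs into the four unit score bins of the 0-4 scale.

    Per group: count, group accuracy (prediction lands in the reference's
    bin), residual mean and sd; plus the overall group accuracy.
    """
    bad = [
        i for i, v in zip(pairs.ids, pairs.reference) if not 0.0 <= v <= 4.0
    ]
    if bad:
        raise ValueError(f"reference scores outside [0, 4] for ids: {bad[:10]}")
    residuals = pairs.predicted - pairs.reference
    groups = []
    correct_total = 0
    for gi, (lo, hi) in enumerate(_GROUPS):
        mask = np.array([_group_of(v) == gi for v in pairs.reference])
        count = int(mask.sum())
        pred_in = [
            _group_of(min(max(p, 0.0), 4.0)) == gi
            for p in pairs.predicted[mask]
        ]
        correct = int(np.sum(pred_in))
        correct_total += correct
        groups.append(
            {
                "range": [lo, hi],
                "count": count,
                "group_accuracy": correct / count if count else float("nan"),
                "residual_mean": float(residuals[mask].mean()) if count else float("nan"),
                "residual_sd": float(residuals[mask].std(ddof=0)) if count else float("nan"),
            }
        )
    return {
        "groups": groups,
        "overall_accuracy": correct_total / len(pairs),
        "n": len(pairs),
    }


def scan_score(slice_scores: Sequence[float]) -> float:
    """Scan-level quality: arithmetic mean of its slice-wise scores."""
    arr = np.asarray(list(slice_scores), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("scan_score requires at least one slice score")
    return float(arr.mean())


def export_residuals(pairs: ScorePairs, path) -> None:
    """CSV of id, reference, predicted, residual (predicted - reference) —
    the substrate for external paired significance testing."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "image_id": pairs.ids,
            "reference": pairs.reference,
            "predicted": pairs.predicted,
            "residual": pairs.predicted - pairs.reference,
        }
    )
    df.to_csv(path, index=False)


def render_report_plots(pairs: ScorePairs, out_dir) -> list:
    """Optional diagnostics: prediction scatter, residual KDE and box plots
    per score group.  Returns the written file paths."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.scatter(pairs.reference, pairs.predicted, s=12, alpha=0.6)
    lim = [min(pairs.reference.min(), pairs.predicted.min()),
           max(pairs.reference.max(), pairs.predicted.max())]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("reference score")
    ax.set_ylabel("predicted score")
    fig.tight_layout()
    p = out / "scatter.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    residuals = pairs.predicted - pairs.reference
    group_idx = [_group_of(min(max(v, 0.0), 4.0)) for v in pairs.reference]
    by_group = [
        residuals[np.array(group_idx) == g] for g in range(len(_GROUPS))
    ]
    fig, axes = plt.subplots(1, 2, figsize=(8.4, 4))
    for g, res in enumerate(by_group):
        if len(res) > 1:
            kde = stats.gaussian_kde(res)
            xs = np.linspace(res.min() - 0.2, res.max() + 0.2, 200)
            axes[0].plot(xs, kde(xs), label=f"[{_GROUPS[g][0]:g},{_GROUPS[g][1]:g}]")
    axes[0].set_xlabel("residual")
    axes[0].set_ylabel("density")
    axes[0].legend(fontsize=7)
    axes[1].boxplot([r for r in by_group if len(r)],
                    tick_labels=[f"{g[0]:g}-{g[1]:g}" for g, r in zip(_GROUPS, by_group) if len(r)])
    axes[1].set_ylabel("residual")
    fig.tight_layout()
    p = out / "residuals_by_group.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written


@dataclass
class EvalReport:
    """Full evaluation: correlations, aggregate s, R^2 and range analysis."""

    r: float
    rho: float
    tau: float
    s: float
    r2: float
    n: int
    residuals: np.ndarray
    range_groups: dict | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["residuals"] = [float(x) for x in self.residuals]
        return d

    def summary_row(self) -> dict:
        return {"r": self.r, "rho": self.rho, "tau": self.tau, "s": self.s,
                "r2": self.r2, "n": self.n}


def evaluate_pairs(pairs: ScorePairs, range_wise: bool | None = None) -> EvalReport:
    """Compute the full report; range-wise analysis runs when all reference
    scores sit in [0, 4] (or when forced via ``range_wise=True``)."""
    r = pearson_r(pairs)
    rho = spearman_rho(pairs)
    tau = kendall_tau(pairs)
    if range_wise is None:
        range_wise = bool(np.all((pairs.reference >= 0) & (pairs.reference <= 4)))
    return EvalReport(
        r=r,
        rho=rho,
        tau=tau,
        s=overall_s(r, rho, tau),
        r2=r_squared(pairs),
        n=len(pairs),
        residuals=pairs.predicted - pairs.reference,
        range_groups=range_wise_eval(pairs) if range_wise else None,
    )
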