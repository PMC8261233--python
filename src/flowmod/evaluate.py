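"""Intention-to-test pooling and diagnostic performance evaluation.

After the blinded samples are unblinded against the reference
radioimmunoassay (RIA), samples are pooled intention-to-test style:
RIA-positive blinded samples join the known seropositive group, RIA-negative
ones join the healthy controls.  Diagnostic performance of the screening
% immunomodulation is then summarized as an empirical ROC curve / AUROC
(seropositive group vs the pooled healthy / autonomic / other-neurological /
SLE negatives; seronegative-AAG and probable-AAG sera are excluded from the
reference sets but reported descriptively), sensitivity and specificity at
the decision limit, and Spearman rank correlations with RIA values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"

#: Final groups after intention-to-test pooling.
FINAL_GROUPS = (
    "seropositive_AAG",
    "healthy_control_pooled",
    "autonomic_not_AAG",
    "other_neuro",
    "SLE",
    "seronegative_AAG",
    "probable_AAG",
)

_REFERENCE_LABEL = {
    "seropositive_AAG": POSITIVE,
    "healthy_control_pooled": NEGATIVE,
    "autonomic_not_AAG": NEGATIVE,
    "other_neuro": NEGATIVE,
    "SLE": NEGATIVE,
    "seronegative_AAG": EXCLUDED,
    "probable_AAG": EXCLUDED,
}


class EvaluationError(ValueError):
    """Invalid evaluation input."""


@dataclass(frozen=True)
class GroupAssignment:
    sample_id: str
    final_group: str
    reference_label: str


@dataclass
class DiagnosticSummary:
    auroc: float
    sensitivity_at_limit: float
    specificity_at_limit: float
    n_pos: int
    n_neg: int
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    spearman_screening_vs_ria: float | None = None
    spearman_titer_vs_ria: float | None = None
    group_counts: dict[str, int] = field(default_factory=dict)


def pool_groups(metadata: pd.DataFrame) -> list[GroupAssignment]:
    """Assign every serum to its final, unblinded group.

    ``metadata`` needs columns ``sample_id``, ``category`` and (for blinded
    samples) ``blinded_truth``.  Blinded RIA-positive samples join
    ``seropositive_AAG``; blinded RIA-negative samples pool with the healthy
    controls.
    """
    out = []
    for row in metadata.itertuples(index=False):
        cat = row.category
        if cat == "blinded":
            truth = getattr(row, "blinded_truth", None)
            if truth not in (POSITIVE, NEGATIVE):
                raise EvaluationError(
                    f"blinded sample {row.sample_id!r} has no unblinded status"
                )
            group = "seropositive_AAG" if truth == POSITIVE else "healthy_control_pooled"
        elif cat == "healthy":
            group = "healthy_control_pooled"
        elif cat in FINAL_GROUPS:
            group = cat
        else:
            raise EvaluationError(f"unknown category {cat!r}")
        out.append(GroupAssignment(row.sample_id, group, _REFERENCE_LABEL[group]))
    return out


def assignments_to_frame(assignments: Sequence[GroupAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "final_group": [a.final_group for a in assignments],
            "reference_label": [a.reference_label for a in assignments],
        }
    )


def _check_two_classes(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels])
    if y.sum() == 0 or y.sum() == len(y):
        raise EvaluationError("ROC needs at least one positive and one negative")
    return y


def empirical_roc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[list[tuple[float, float]], float]:
    """Empirical ROC points (FPR, TPR) and trapezoidal AUROC.

    The trapezoidal area equals the Mann-Whitney probability
    P(score_pos > score_neg) + 0.5 P(tie).
    """
    y = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise EvaluationError("scores and labels length mismatch")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auroc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auroc


def sens_spec_at(
    scores: Sequence[float], labels: Sequence[str], limit: float
) -> tuple[float, float]:
    """Sensitivity and specificity (%) of the score > limit rule."""
    y = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    sens = float(np.mean(s[y == 1] > limit)) * 100.0
    spec = float(np.mean(s[y == 0] <= limit)) * 100.0
    return sens, spec


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise EvaluationError("spearman_rho inputs must have equal length")
    if len(x) < 3:
        raise EvaluationError("spearman_rho needs at least 3 pairs")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise EvaluationError("spearman_rho undefined for zero rank variance")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def plot_roc(roc_points: Sequence[tuple[float, float]], path, auroc: float | None = None) -> None:
    """Write a simple ROC curve image (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [p[0] for p in roc_points]
    tpr = [p[1] for p in roc_points]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, drawstyle="steps-post", color="C0")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    title = "ROC"
    if auroc is not None:
        title += f" (AUROC = {auroc:.3f})"
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def evaluate_cohort(
    results: pd.DataFrame,
    metadata: pd.DataFrame,
    limit: float,
) -> DiagnosticSummary:
    """Full diagnostic summary of a scored cohort.

    ``results`` carries ``sample_id``, ``screening_im`` and optionally
    ``endpoint_titer``; ``metadata`` carries categories, blinded truth and
    RIA values.  Spearman correlations are computed over the seropositive
    samples carrying RIA values (antibody-negative sera have no RIA
    magnitude to rank).
    """
    assignments = pool_groups(metadata)
    aframe = assignments_to_frame(assignments)
    merged = results.merge(aframe, on="sample_id", validate="one_to_one")
    merged = merged.merge(
        metadata[["sample_id", "ria_pM"]], on="sample_id", how="left"
    )

    ref = merged[merged["reference_label"] != EXCLUDED]
    roc_points, auroc = empirical_roc(
        ref["screening_im"].to_numpy(), ref["reference_label"].tolist()
    )
    sens, spec = sens_spec_at(
        ref["screening_im"].to_numpy(), ref["reference_label"].tolist(), limit
    )

    pos = merged[
        (merged["final_group"] == "seropositive_AAG") & merged["ria_pM"].notna()
    ]
    rho_screen = rho_titer = None
    if len(pos) >= 3:
        rho_screen = spearman_rho(pos["screening_im"], pos["ria_pM"])
        if "endpoint_titer" in pos.columns:
            titers = pd.to_numeric(pos["endpoint_titer"], errors="coerce")
            ok = titers.notna()
            if ok.sum() >= 3:
                try:
                    rho_titer = spearman_rho(titers[ok], pos.loc[ok, "ria_pM"])
                except EvaluationError:
                    rho_titer = None  # degenerate: all titers tie

    counts = aframe["final_group"].value_counts().to_dict()
    n_pos = int((ref["reference_label"] == POSITIVE).sum())
    return DiagnosticSummary(
        auroc=auroc,
        sensitivity_at_limit=sens,
        specificity_at_limit=spec,
        n_pos=n_pos,
        n_neg=int(len(ref) - n_pos),
        roc_points=roc_points,
        spearman_screening_vs_ria=rho_screen,
        spearman_titer_vs_ria=rho_titer,
        group_counts=counts,
    )
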