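"""Optional figures: ROC curve and per-outcome probability box plots."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .validation import CohortRecord, RocAnalysis

__all__ = ["plot_roc", "plot_probability_box"]


def plot_roc(roc: RocAnalysis, path) -> None:
    """Empirical ROC curve with the AUC and its 95% CI in the title."""
    fpr = [0.0] + [1.0 - sp for _, sp in reversed(roc.points)]
    tpr = [0.0] + [sn for sn, _ in reversed(roc.points)]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, drawstyle="steps-post", color="tab:blue")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    lo, hi = roc.auc_ci
    ax.set_title(f"AUC {roc.auc:.2f} (95% CI {lo:.2f}-{hi:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_probability_box(records: Sequence[CohortRecord], path) -> None:
    """Predicted CoAo probability by postnatal outcome, as a box plot."""
    coao = [100 * r.predicted_probability for r in records if r.outcome_coao]
    no_coao = [100 * r.predicted_probability for r in records if not r.outcome_coao]
    fig, ax = plt.subplots(figsize=(4.5, 5))
    ax.boxplot([no_coao, coao], tick_labels=["No CoAo", "CoAo"], whis=1.5)
    ax.set_ylabel("Post-test probability of CoAo (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
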