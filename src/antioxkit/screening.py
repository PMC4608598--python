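"""Virtual-screening validation metrics.

A pharmacophore (or any binary) screen called against known actives and
decoys yields a single confusion matrix.  With unscored, binary calls the
ROC curve has one interior operating point, so its area is the trapezoid
through (0,0), (FPR, TPR), (1,1) — algebraically (sensitivity +
specificity)/2.  The enrichment factor compares the hit fraction among the
selected compounds to the active prevalence of the whole collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = ["ScreenOutcome", "binary_roc_auc", "enrichment_factor", "HitRate",
           "hit_rate"]


@dataclass(frozen=True)
class ScreenOutcome:
    """Confusion counts of a binary screen against labelled compounds."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def n_active(self) -> int:
        return self.tp + self.fn

    @property
    def n_inactive(self) -> int:
        return self.fp + self.tn


def binary_roc_auc(o: ScreenOutcome) -> float:
    """ROC AUC of a binary classifier via the single-operating-point trapezoid."""
    if o.n_active == 0 or o.n_inactive == 0:
        raise DomainError("both classes must be non-empty")
    tpr = o.tp / o.n_active
    fpr = o.fp / o.n_inactive
    return float(np.trapezoid([0.0, tpr, 1.0], [0.0, fpr, 1.0]))


def enrichment_factor(o: ScreenOutcome) -> float:
    """Hit fraction among selected compounds over the active prevalence."""
    selected = o.tp + o.fp
    if selected == 0:
        raise DomainError("no compounds selected")
    if o.n_active == 0:
        raise DomainError("no active compounds in the collection")
    precision = o.tp / selected
    prevalence = o.n_active / (o.n_active + o.n_inactive)
    return float(precision / prevalence)


@dataclass(frozen=True)
class HitRate:
    """A campaign hit rate with its rounded display form."""

    percent: float

    @property
    def display(self) -> str:
        return f"{round(self.percent)}%"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.display


def hit_rate(n_hits: int, n_tested: int) -> HitRate:
    """Percentage of tested compounds that were active."""
    if n_tested <= 0:
        raise DomainError("n_tested must be > 0")
    if not (0 <= n_hits <= n_tested):
        raise DomainError("require 0 <= n_hits <= n_tested")
    return HitRate(100.0 * n_hits / n_tested)
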