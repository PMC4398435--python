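"""Thresholding, confusion-matrix metrics, and the joint expert/Kappa gate.

A continuous suitability prediction is made binary at the 10-percentile
training-presence threshold (the suitability below which the lowest 10%
of training presences fall). Confusion counts treat background points as
absences. A model is "modellable" only if Cohen's kappa exceeds 0.4 AND an
expert rated it good or medium; either a low kappa or a poor rating makes
it "unmodellable". AUC is computed for completeness (rank statistic of
presence vs background scores) but never used for selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "EvalMetrics",
    "ExpertRating",
    "ValidationDecision",
    "threshold_10ptp",
    "confusion",
    "compute_metrics",
    "validation_gate",
    "select_variant",
    "VARIANTS",
]

#: Model variants: input data x habitat restriction.
#:   i   pre+post data, climate only
#:   ii  pre+post data, restricted to occupied land classes
#:   iii post-only data, climate only
#:   iv  post-only data, restricted to occupied land classes
VARIANTS = ("i", "ii", "iii", "iv")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("negative confusion count")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalMetrics:
    auc: float
    omission_rate: float
    sensitivity: float
    specificity: float
    proportion_correct: float
    kappa: float
    tss: float
    degenerate_kappa: bool = False


@dataclass(frozen=True)
class ExpertRating:
    species: str
    rating: Literal["good", "medium", "poor"]
    chosen_variant: str | None = None


@dataclass(frozen=True)
class ValidationDecision:
    species: str
    kappa: float
    rating: str
    decision: Literal["modellable", "unmodellable"]


def load_ratings(path):
    """Read an expert-ratings CSV (`species,rating,chosen_variant`)."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"species", "rating"} - set(df.columns)
    if missing:
        raise ValueError(f"ratings CSV missing columns: {sorted(missing)}")
    if "chosen_variant" not in df.columns:
        df["chosen_variant"] = None
    bad = set(df["rating"].dropna()) - {"good", "medium", "poor"}
    if bad:
        raise ValueError(f"unknown expert ratings: {sorted(bad)}")
    if df["species"].duplicated().any():
        raise ValueError("more than one rating for a species")
    return df


def threshold_10ptp(training_presence_suitabilities, percentile: float = 10.0) -> float:
    """10-percentile training presence threshold, lower-interpolation.

    Cells with suitability >= the returned value are called presence.
    """
    v = np.asarray(training_presence_suitabilities, dtype=float)
    if v.size == 0:
        raise ValueError("no training presence suitabilities")
    return float(np.percentile(v, percentile, method="lower"))


def confusion(presence_predictions, background_predictions) -> ConfusionCounts:
    """Tally binary predictions; background points count as absences."""
    p = np.asarray(presence_predictions, dtype=bool)
    b = np.asarray(background_predictions, dtype=bool)
    if p.size == 0 or b.size == 0:
        raise ValueError("need >=1 presence and >=1 background evaluation point")
    return ConfusionCounts(
        tp=int(p.sum()), fn=int((~p).sum()), fp=int(b.sum()), tn=int((~b).sum())
    )


def rank_auc(presence_scores, background_scores) -> float:
    """AUC as P(score_presence > score_background) + 0.5 P(tie)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    ranks = rankdata(np.concatenate([p, b]))
    # Mann-Whitney U from the presence rank-sum; midranks handle ties.
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def compute_metrics(
    counts: ConfusionCounts,
    presence_scores=None,
    background_scores=None,
) -> EvalMetrics:
    """Confusion-matrix statistics plus rank AUC when scores are given.

    kappa = (Po - Pe)/(1 - Pe) with Po the proportion correct and Pe the
    chance agreement from the marginal products. Degenerate margins
    (Pe = 1) report kappa 0 with a flag.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    n = counts.total
    sensitivity = tp / (tp + fn) if tp + fn else np.nan
    specificity = tn / (tn + fp) if tn + fp else np.nan
    omission = fn / (tp + fn) if tp + fn else np.nan
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
    degenerate = bool(abs(1 - pe) < 1e-15)
    if degenerate:
        warnings.warn("degenerate margins (Pe = 1); kappa reported as 0")
        kappa = 0.0
    else:
        kappa = (po - pe) / (1 - pe)
    tss = sensitivity + specificity - 1
    if presence_scores is not None and background_scores is not None:
        auc = rank_auc(presence_scores, background_scores)
    else:
        auc = np.nan
    return EvalMetrics(
        auc=auc,
        omission_rate=omission,
        sensitivity=sensitivity,
        specificity=specificity,
        proportion_correct=po,
        kappa=kappa,
        tss=tss,
        degenerate_kappa=degenerate,
    )


def validation_gate(
    species: str, kappa: float, rating: str | None, kappa_cut: float = 0.4
) -> ValidationDecision:
    """Joint gate: modellable iff kappa > 0.4 and rating good/medium."""
    if rating is None:
        raise ValueError(f"{species}: no expert rating; species unresolved")
    if rating not in ("good", "medium", "poor"):
        raise ValueError(f"unknown expert rating {rating!r}")
    ok = (kappa > kappa_cut) and rating in ("good", "medium")
    return ValidationDecision(
        species=species,
        kappa=float(kappa),
        rating=rating,
        decision="modellable" if ok else "unmodellable",
    )


#: Preference order for kappa ties: habitat-restricted beats unrestricted,
#: then pre+post data beats post-only. ii > iv > i > iii.
_TIE_ORDER = {"ii": 0, "iv": 1, "i": 2, "iii": 3}


def select_variant(
    kappas: Mapping[str, float], expert_choice: str | None = None
) -> str:
    """Pick the model variant: the expert's choice wins outright; without
    one, the highest kappa wins with the deterministic tie-break
    (habitat-restricted first, then pre+post input data)."""
    if expert_choice is not None:
        if expert_choice not in VARIANTS:
            raise ValueError(f"unknown variant {expert_choice!r}")
        return expert_choice
    if not kappas:
        raise ValueError("no variants to select from")
    return max(kappas, key=lambda v: (kappas[v], -_TIE_ORDER[v]))
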