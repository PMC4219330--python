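"""Evaluation: accuracy, ROC sweeps, exposure histograms and paralog pairs.

The paralog-pair benchmark probes homology independence: pairs of
paralogous proteins whose experimentally known locations differ. A pair is
counted correct only when both members are predicted in their true class.
Significance comes from a Monte-Carlo null in which every protein
independently receives one of the four classes uniformly at random, so a
pair is correct with probability 1/16 (an alternative null that assigns
each pair an ordered pair of distinct classes, success 1/12, is available
via ``null="per_pair"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .curation import CLASS_ORDER
from .exposure import AA_INDEX, DEFAULT_RANGE_BOUNDARIES, ExposlocError

__all__ = [
    "accuracy",
    "roc_points",
    "roc_auc",
    "exposure_distribution",
    "exposure_range_distribution",
    "ParalogPair",
    "PairEvaluation",
    "evaluate_pairs",
    "permutation_pvalue",
    "exact_pair_pvalue",
    "merge_nucleocytoplasmic",
]


def accuracy(predictions: Sequence, truths: Sequence) -> float:
    """Fraction of predictions equal to the truth."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths disagree in length")
    if predictions.size == 0:
        raise ValueError("accuracy of an empty set is undefined")
    return float(np.mean(predictions == truths))


def roc_points(scores: Sequence[float], truths: Sequence) -> np.ndarray:
    """Threshold sweep -> array of (threshold, TPR, FPR) rows.

    One row per distinct score, descending; an example is called positive
    when its score >= threshold, so both rates grow monotonically along the
    sweep. Requires at least one positive and one negative truth.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths).astype(bool)
    if scores.shape != truths.shape:
        raise ValueError("scores and truths disagree in length")
    n_pos = int(truths.sum())
    n_neg = int((~truths).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    rows = []
    for thr in np.unique(scores)[::-1]:
        called = scores >= thr
        tpr = float((called & truths).sum() / n_pos)
        fpr = float((called & ~truths).sum() / n_neg)
        rows.append((float(thr), tpr, fpr))
    return np.asarray(rows)


def roc_auc(scores, truths) -> float:
    """Area under the ROC curve by trapezoid over the sweep (0,0) -> (1,1)."""
    pts = roc_points(scores, truths)
    fpr = np.concatenate([[0.0], pts[:, 2], [1.0]])
    tpr = np.concatenate([[0.0], pts[:, 1], [1.0]])
    return float(np.trapezoid(tpr, fpr))


def exposure_distribution(profiles: Iterable, aa: str,
                          bins=10) -> Optional[np.ndarray]:
    """Normalized histogram of RSA values for one amino-acid type.

    ``bins`` is an integer (equal-width bins over [0, 1]) or explicit bin
    edges. Uses structure-derived residues (those carrying an RSA value);
    returns ``None`` when the amino acid does not occur — the documented
    empty-distribution signal.
    """
    aa = aa.upper()
    if aa not in AA_INDEX:
        raise ValueError(f"unknown amino acid {aa!r}")
    values = [rec.rsa for p in profiles for rec in p.residues
              if rec.aa == aa and rec.rsa is not None]
    if not values:
        return None
    if np.isscalar(bins):
        bins = np.linspace(0.0, 1.0, int(bins) + 1)
    hist, _ = np.histogram(values, bins=bins)
    return hist / hist.sum()


def exposure_range_distribution(profiles: Iterable, aa: str,
                                n_ranges: int = DEFAULT_RANGE_BOUNDARIES.n_ranges
                                ) -> Optional[np.ndarray]:
    """Fraction of an amino acid's residues in each exposure range (1..k).

    Works for both structure-derived and predicted profiles (ranges are
    always present). Returns ``None`` when the amino acid does not occur.
    """
    aa = aa.upper()
    if aa not in AA_INDEX:
        raise ValueError(f"unknown amino acid {aa!r}")
    counts = np.zeros(n_ranges)
    for p in profiles:
        for rec in p.residues:
            if rec.aa == aa:
                counts[rec.range_index - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else None


# ---------------------------------------------------------------------------
# Paralog pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParalogPair:
    """Two paralogous proteins with differing true location classes."""

    id1: str
    class1: str
    id2: str
    class2: str

    def __post_init__(self):
        for cls in (self.class1, self.class2):
            if cls not in CLASS_ORDER:
                raise ValueError(f"unknown location class {cls!r}")
        if self.class1 == self.class2:
            raise ValueError(
                f"pair ({self.id1}, {self.id2}): true classes must differ")


@dataclass(frozen=True)
class PairEvaluation:
    """Counts over a paralog-pair benchmark."""

    n_pairs: int
    same_location: int    # pairs whose two predicted classes coincide
    both_correct: int     # pairs with both members correctly predicted
    proteins_correct: int  # correctly predicted member proteins (<= 2 * n_pairs)

    def __post_init__(self):
        if not (0 <= self.both_correct <= self.n_pairs
                and 0 <= self.same_location <= self.n_pairs
                and 0 <= self.proteins_correct <= 2 * self.n_pairs):
            raise ValueError("inconsistent pair-evaluation counts")


def evaluate_pairs(pairs: Sequence[ParalogPair],
                   predictions: Mapping[str, str]) -> PairEvaluation:
    """Score predicted classes against a paralog-pair benchmark."""
    same = correct_pairs = correct_proteins = 0
    for pair in pairs:
        for pid in (pair.id1, pair.id2):
            if pid not in predictions:
                raise KeyError(f"no prediction for protein {pid!r}")
        p1, p2 = predictions[pair.id1], predictions[pair.id2]
        same += p1 == p2
        hits = (p1 == pair.class1) + (p2 == pair.class2)
        correct_proteins += hits
        correct_pairs += hits == 2
    return PairEvaluation(len(pairs), same, correct_pairs, correct_proteins)


_NULL_P = {"per_protein": 1.0 / 16.0, "per_pair": 1.0 / 12.0}


def permutation_pvalue(n_pairs: int, observed_correct: int, reps: int = 10 ** 6,
                       seed: Optional[int] = None, null: str = "per_protein",
                       plus_one: bool = False) -> float:
    """Monte-Carlo tail probability of >= ``observed_correct`` correct pairs.

    Under the default null each protein draws one of the four classes
    uniformly and independently, so a pair is correct with probability
    1/16; ``null="per_pair"`` instead assigns each pair an ordered pair of
    distinct classes (success 1/12). The estimate is the plain fraction
    count/reps; ``plus_one`` switches to (count+1)/(reps+1).
    """
    if not 0 <= observed_correct <= n_pairs:
        raise ValueError("observed_correct must lie in 0..n_pairs")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    p = _NULL_P[null]
    rng = np.random.default_rng(seed)
    sims = rng.binomial(n_pairs, p, size=int(reps))
    count = int((sims >= observed_correct).sum())
    if plus_one:
        return (count + 1) / (reps + 1)
    return count / reps


def exact_pair_pvalue(n_pairs: int, observed_correct: int,
                      null: str = "per_protein") -> float:
    """Exact binomial tail P(X >= observed), X ~ Binom(n_pairs, null p)."""
    from scipy.stats import binom

    return float(binom.sf(observed_correct - 1, n_pairs, _NULL_P[null]))


def merge_nucleocytoplasmic(nuclear: float, cytoplasmic: float,
                            all_scores: Mapping[str, float]) -> bool:
    """Score-merging rule for tools without a nucleocytoplasmic class.

    Normalize all class scores to sum one; the protein is treated as
    nucleocytoplasmic iff normalized(nuclear) + normalized(cytoplasmic)
    strictly exceeds 0.5. ``all_scores`` must include the nuclear and
    cytoplasmic scores among its entries.
    """
    if nuclear < 0 or cytoplasmic < 0 or any(v < 0 for v in all_scores.values()):
        raise ValueError("class scores must be non-negative")
    total = float(sum(all_scores.values()))
    if total == 0:
        raise ValueError("all-zero score vector: merging rule undefined")
    return (nuclear + cytoplasmic) / total > 0.5
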