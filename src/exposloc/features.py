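"""Range-restricted amino-acid composition features.

A protein's composition vector has 20 components (fixed alphabetical
one-letter order), each the fraction of its residues of that type; the
components sum to 1. Restricting the count to residues in a subset of the
six exposure ranges gives a *range-restricted* composition vector, and
concatenating two of them gives a 40-component feature, e.g. the buried
half (ranges 1 2 3) next to the exposed half (ranges 4 5 6).

The canonical intermediate is a per-protein 6 x 20 count matrix (residues
per exposure range and amino acid); every feature spec is a linear
read-out of it, so featurization for several specs shares one pass over
the profile.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exposure import AA_INDEX, AMINO_ACIDS, ExposureProfile

__all__ = [
    "SPEC_A",
    "SPEC_B",
    "SPEC_C",
    "DEFAULT_SPECS",
    "N_RANGES",
    "validate_spec",
    "range_aa_counts",
    "composition_vector",
    "feature_vector",
    "counts_to_features",
    "spec_feature_names",
    "CompositionFeaturizer",
]

N_RANGES = 6

FeatureSpec = Tuple[Tuple[int, ...], ...]

#: Buried / exposed halves — the 40-component spec that feeds stack slot A.
SPEC_A: FeatureSpec = ((1, 2, 3), (4, 5, 6))
#: Most-buried range against everything else — stack slot B.
SPEC_B: FeatureSpec = ((1,), (2, 3, 4, 5, 6))
#: Whole-protein composition — stack slot C.
SPEC_C: FeatureSpec = ((1, 2, 3, 4, 5, 6),)
DEFAULT_SPECS = (SPEC_A, SPEC_B, SPEC_C)


def validate_spec(spec: FeatureSpec) -> FeatureSpec:
    """Normalize and validate a feature spec (1 or 2 ordered range sets)."""
    spec = tuple(tuple(int(r) for r in rs) for rs in spec)
    if not 1 <= len(spec) <= 2:
        raise ValueError(f"feature spec must hold 1 or 2 range sets, got {len(spec)}")
    for rs in spec:
        if not rs:
            raise ValueError("empty range set in feature spec")
        if sorted(set(rs)) != list(rs):
            raise ValueError(f"range set must be unique and ascending: {rs}")
        if rs[0] < 1 or rs[-1] > N_RANGES:
            raise ValueError(f"range indices must lie in 1..{N_RANGES}: {rs}")
    return spec


def range_aa_counts(profile: ExposureProfile) -> np.ndarray:
    """Count covered residues per (exposure range, amino acid): 6 x 20 floats."""
    counts = np.zeros((N_RANGES, len(AMINO_ACIDS)))
    for rec in profile.residues:
        counts[rec.range_index - 1, AA_INDEX[rec.aa]] += 1
    return counts


def _normalize_block(block: np.ndarray) -> np.ndarray:
    total = block.sum()
    # Empty range sets yield the all-zero vector, keeping dimensionality fixed.
    return block / total if total > 0 else np.zeros_like(block)


def composition_vector(profile: ExposureProfile, ranges: Sequence[int]) -> np.ndarray:
    """Amino-acid fractions among covered residues whose range is in ``ranges``."""
    (ranges,) = validate_spec((tuple(ranges),))
    counts = range_aa_counts(profile)
    return _normalize_block(counts[[r - 1 for r in ranges]].sum(axis=0))


def feature_vector(profile: ExposureProfile, spec: FeatureSpec) -> np.ndarray:
    """Concatenated composition vectors for each range set of ``spec`` (20 or 40)."""
    spec = validate_spec(spec)
    counts = range_aa_counts(profile)
    return counts_to_features(counts[None, :, :], spec)[0]


def counts_to_features(counts: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Vectorized featurization: (n, 6, 20) or (n, 120) counts -> (n, 20*len(spec))."""
    spec = validate_spec(spec)
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 2:
        counts = counts.reshape(counts.shape[0], N_RANGES, len(AMINO_ACIDS))
    blocks = []
    for rs in spec:
        block = counts[:, [r - 1 for r in rs], :].sum(axis=1)
        totals = block.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            block = np.where(totals > 0, block / np.where(totals > 0, totals, 1.0), 0.0)
        blocks.append(block)
    return np.hstack(blocks)


def spec_feature_names(spec: FeatureSpec) -> list:
    """Column names like ``r123_A .. r456_Y`` for a featurization table."""
    spec = validate_spec(spec)
    names = []
    for rs in spec:
        tag = "r" + "".join(str(r) for r in rs)
        names.extend(f"{tag}_{aa}" for aa in AMINO_ACIDS)
    return names


def count_feature_names() -> list:
    """Column names for the canonical 120-component count representation."""
    return [f"n{r}_{aa}" for r in range(1, N_RANGES + 1) for aa in AMINO_ACIDS]


class CompositionFeaturizer(TransformerMixin, BaseEstimator):
    """Profiles -> canonical per-range amino-acid count matrix (n, 120).

    Stateless transformer: the output feeds any downstream feature spec via
    :func:`counts_to_features`, so classifiers over different range sets
    share one featurization pass and compose in sklearn pipelines.
    """

    def fit(self, X: Iterable[ExposureProfile], y=None):
        return self

    def transform(self, X: Iterable[ExposureProfile]) -> np.ndarray:
        rows = [range_aa_counts(p).ravel() for p in X]
        if not rows:
            return np.zeros((0, N_RANGES * len(AMINO_ACIDS)))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(count_feature_names(), dtype=object)
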