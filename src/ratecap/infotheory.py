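"""Discrete entropy and mutual information for paired categorical data.

Everything here works on plug-in (empirical-frequency) estimates over a
*declared* category scale: contingency tables always span the full rating
scale, including categories that were never used, so that table shapes stay
stable across participants and blocks.  Zero cells contribute nothing to any
information quantity (``0 log 0 == 0`` by continuity), so spanning the full
scale never changes an entropy or a mutual information — it only matters for
bias corrections that count occupied categories.

All quantities are in bits (log base 2).  One bit is the information needed
to decide between two equally likely alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DiscreteDistribution",
    "ContingencyTable",
    "entropy_bits",
    "contingency_from_pairs",
    "mutual_information_bits",
    "miller_madow_bits",
    "mi_uniform_input",
]

_PROB_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a distribution, table or matrix fails its invariants."""


@dataclass(frozen=True)
class DiscreteDistribution:
    """A probability distribution over an ordered list of categories."""

    categories: tuple
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "categories", tuple(self.categories))
        if p.ndim != 1 or len(self.categories) != p.size:
            raise ValidationError("categories and probabilities must align 1:1")
        if np.any(p < 0):
            raise ValidationError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > _PROB_TOL:
            raise ValidationError(
                f"probabilities sum to {p.sum()!r}, not 1 within {_PROB_TOL}"
            )

    @classmethod
    def uniform(cls, categories: Iterable) -> "DiscreteDistribution":
        cats = tuple(categories)
        return cls(cats, np.full(len(cats), 1.0 / len(cats)))


@dataclass(frozen=True)
class ContingencyTable:
    """Joint counts of (input category, output category).

    ``counts[i, j]`` is the number of observations with input category
    ``input_categories[i]`` and output category ``output_categories[j]``.
    Houses the empirical joint p(x, y) = counts / n and its marginals.
    """

    counts: np.ndarray
    input_categories: tuple = field(default=None)
    output_categories: tuple = field(default=None)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        if np.any(c < 0):
            raise ValidationError("counts must be non-negative")
        if not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValidationError("counts must be integers")
        c = c.astype(np.int64)
        object.__setattr__(self, "counts", c)
        in_cats = self.input_categories
        out_cats = self.output_categories
        in_cats = tuple(range(c.shape[0])) if in_cats is None else tuple(in_cats)
        out_cats = tuple(range(c.shape[1])) if out_cats is None else tuple(out_cats)
        if (len(in_cats), len(out_cats)) != c.shape:
            raise ValidationError("category lists must match the counts shape")
        object.__setattr__(self, "input_categories", in_cats)
        object.__setattr__(self, "output_categories", out_cats)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def joint(self) -> np.ndarray:
        """Empirical joint probabilities p(x, y); requires n >= 1."""
        if self.n == 0:
            raise ValidationError("empty table: n must be >= 1 for estimation")
        return self.counts / self.n

    def input_marginal(self) -> DiscreteDistribution:
        return DiscreteDistribution(self.input_categories,
                                    self.counts.sum(axis=1) / self.n)

    def output_marginal(self) -> DiscreteDistribution:
        return DiscreteDistribution(self.output_categories,
                                    self.counts.sum(axis=0) / self.n)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T, self.output_categories,
                                self.input_categories)

    def restrict_to_observed(self) -> "ContingencyTable":
        """Drop all-zero rows and columns (observed-categories view).

        Mathematically irrelevant for plug-in entropy/MI; changes the
        declared-scale variant of bias corrections.
        """
        rows = self.counts.sum(axis=1) > 0
        cols = self.counts.sum(axis=0) > 0
        return ContingencyTable(
            self.counts[np.ix_(rows, cols)],
            tuple(np.asarray(self.input_categories, dtype=object)[rows]),
            tuple(np.asarray(self.output_categories, dtype=object)[cols]),
        )


def entropy_bits(dist: DiscreteDistribution | Sequence[float]) -> float:
    """Shannon entropy H = -sum p log2 p, in bits.

    Accepts a :class:`DiscreteDistribution` or a bare probability vector
    (validated the same way).  ``0 log 0`` contributes 0.
    """
    if not isinstance(dist, DiscreteDistribution):
        p = np.asarray(dist, dtype=float)
        dist = DiscreteDistribution(tuple(range(p.size)), p)
    p = dist.probabilities
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def contingency_from_pairs(
    pairs: Iterable[tuple],
    scale: Sequence,
    output_scale: Sequence | None = None,
) -> ContingencyTable:
    """Count (input, output) pairs into a table spanning the full scale.

    Every label must belong to the declared scale; all-zero rows/columns are
    retained so the table shape is scale x scale regardless of which
    categories were actually used.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("pairs must be non-empty")
    in_cats = tuple(scale)
    out_cats = tuple(output_scale) if output_scale is not None else in_cats
    in_index = {c: i for i, c in enumerate(in_cats)}
    out_index = {c: j for j, c in enumerate(out_cats)}
    counts = np.zeros((len(in_cats), len(out_cats)), dtype=np.int64)
    for x, y in pairs:
        if x not in in_index:
            raise ValidationError(f"input label {x!r} not in declared scale")
        if y not in out_index:
            raise ValidationError(f"output label {y!r} not in declared scale")
        counts[in_index[x], out_index[y]] += 1
    return ContingencyTable(counts, in_cats, out_cats)


def _mi_from_joint(joint: np.ndarray) -> float:
    """MI in bits of an exact (or empirical) joint probability matrix."""
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = joint[mask] / (px @ py)[mask]
    return float((joint[mask] * np.log2(ratio)).sum())


def mutual_information_bits(table: ContingencyTable) -> float:
    """Plug-in mutual information I(X:Y) of a contingency table, in bits.

    I = sum_x sum_y p(x,y) log2[ p(x,y) / (p(x) p(y)) ], with empirical
    probabilities cell/n.  Symmetric under transposition; bounded by the
    marginal entropies.  Upward-biased in small samples (see
    :func:`miller_madow_bits`).
    """
    return _mi_from_joint(table.joint())


def miller_madow_bits(
    table: ContingencyTable, category_counting: str = "occupied"
) -> float:
    """Miller–Madow first-order bias-corrected mutual information, in bits.

    Subtracts (K_x - 1)(K_y - 1) / (2 n ln 2) from the plug-in value and
    clips at 0.  With ``category_counting="occupied"`` (default) K_x, K_y
    count categories with nonzero marginal counts — the standard form, which
    does not over-correct sparse tables.  ``"declared"`` uses the full
    declared scale sizes instead.
    """
    plugin = mutual_information_bits(table)
    if category_counting == "occupied":
        kx = int((table.counts.sum(axis=1) > 0).sum())
        ky = int((table.counts.sum(axis=0) > 0).sum())
    elif category_counting == "declared":
        kx, ky = table.counts.shape
    else:
        raise ValueError(
            "category_counting must be 'occupied' or 'declared'"
        )
    correction = (kx - 1) * (ky - 1) / (2.0 * table.n * np.log(2))
    return max(0.0, plugin - correction)


def mi_uniform_input(confusion: np.ndarray) -> float:
    """Mutual information of a channel driven by a uniform input, in bits.

    ``confusion`` is row-stochastic: one row per input category, giving the
    probability of each output category.  This is the information actually
    transmitted when every input is presented equally often — the analytic
    ground truth against which the empirical estimation pipeline is checked
    (not the channel's true capacity, which would optimize over inputs).
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2:
        raise ValidationError("confusion matrix must be 2-D")
    if np.any(conf < 0):
        raise ValidationError("confusion matrix entries must be non-negative")
    row_sums = conf.sum(axis=1)
    bad = np.where(np.abs(row_sums - 1.0) > _PROB_TOL)[0]
    if bad.size:
        raise ValidationError(
            f"row(s) {bad.tolist()} sum to {row_sums[bad].tolist()}, not 1"
        )
    joint = conf / conf.shape[0]
    return _mi_from_joint(joint)
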