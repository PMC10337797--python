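"""From long-format rating tables to mutual-information curves and capacity.

The analysis treats a rater as a noisy channel.  For each participant,
block and stimulus, the "input" category is the participant's own mean
rating of that stimulus within the block (rounded to an integer on the
rating scale) — their ground truth for the stimulus — and each individual
rating is an "output".  Mutual information between input and output, in
bits, measures how much each single rating tells you about the rater's
settled judgment.  Sweeping the number of distinct stimuli per block sweeps
the source entropy log2(k); the MI-vs-source-entropy curve rises and
saturates, and the saturation level is the rater's transmission capacity.

Because the input mean contains the output rating, a leave-one-out mode is
provided in which each rating is paired with the rounded mean of the
*remaining* repetitions of that stimulus.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .infotheory import (
    ContingencyTable,
    ValidationError,
    contingency_from_pairs,
    miller_madow_bits,
    mutual_information_bits,
)

__all__ = [
    "RatingRecord",
    "RatingDataset",
    "MICurvePoint",
    "CapacityEstimate",
    "rounded_mean_input",
    "loo_inputs",
    "participant_block_mi",
    "aggregate_curve",
    "fit_capacity",
    "sevenpoint_to_tenpoint",
    "pearson_validate",
    "curve_to_frame",
]

logger = logging.getLogger("ratecap")

REQUIRED_COLUMNS = ("participant", "block", "stimulus", "repetition", "rating")

Rounding = Literal["half-even", "half-up"]
Mode = Literal["plugin", "loo"]


@dataclass(frozen=True)
class RatingRecord:
    """One observed rating with its experimental coordinates."""

    participant_id: object
    block_id: object
    stimulus_id: object
    repetition: int
    rating: int


@dataclass
class RatingDataset:
    """A validated collection of ratings plus the experimental design.

    ``frame`` is long-format with columns
    ``participant, block, stimulus, repetition, rating``; ratings are
    integers on the declared scale.  The design summary (which stimuli each
    block contains, and how many repetitions each stimulus gets) is inferred
    from the data unless supplied.
    """

    frame: pd.DataFrame
    scale_min: int = 1
    scale_max: int = 10
    repetitions: int | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required column(s): {missing}")
        if len(df) == 0:
            raise ValidationError("dataset contains no records")
        ratings = df["rating"]
        if not np.all(np.equal(np.mod(ratings, 1), 0)):
            raise ValidationError("ratings must be integers")
        df = df.copy()
        df["rating"] = df["rating"].astype(int)
        out_of_scale = df[(df["rating"] < self.scale_min)
                          | (df["rating"] > self.scale_max)]
        if len(out_of_scale):
            bad = out_of_scale["rating"].unique().tolist()
            raise ValidationError(
                f"rating(s) {bad} outside scale "
                f"[{self.scale_min}, {self.scale_max}]"
            )
        keys = ["participant", "block", "stimulus", "repetition"]
        if df.duplicated(subset=keys).any():
            dup = df[df.duplicated(subset=keys, keep=False)].iloc[0]
            raise ValidationError(
                "duplicate (participant, block, stimulus, repetition): "
                f"{tuple(dup[k] for k in keys)}"
            )
        self.frame = df.reset_index(drop=True)
        if self.repetitions is None:
            counts = df.groupby(["participant", "block", "stimulus"],
                                sort=False).size()
            self.repetitions = int(counts.mode().iloc[0])

    @property
    def scale(self) -> range:
        return range(self.scale_min, self.scale_max + 1)

    @property
    def participants(self) -> list:
        return list(pd.unique(self.frame["participant"]))

    def design_summary(self) -> dict:
        """block id -> sorted list of stimulus ids appearing in that block."""
        return {
            b: sorted(g["stimulus"].unique().tolist())
            for b, g in self.frame.groupby("block", sort=False)
        }

    def block_sizes(self) -> dict:
        return {b: len(s) for b, s in self.design_summary().items()}

    def records(self) -> Iterable[RatingRecord]:
        for row in self.frame.itertuples(index=False):
            yield RatingRecord(row.participant, row.block, row.stimulus,
                               int(row.repetition), int(row.rating))

    def complete_participants(self, warn: bool = True) -> list:
        """Participants with every designed (block, stimulus) cell complete.

        Incomplete participants are reported (and later dropped) rather than
        imputed: mutual information on partial tables silently changes n.
        """
        design = self.design_summary()
        ok = []
        for p, g in self.frame.groupby("participant", sort=False):
            missing = _missing_cells(g, design, self.repetitions)
            if missing:
                if warn:
                    msg = (f"dropping incomplete participant {p!r}: "
                           f"missing {missing[:5]}"
                           + (" ..." if len(missing) > 5 else ""))
                    logger.warning(msg)
                    warnings.warn(msg, stacklevel=2)
            else:
                ok.append(p)
        return ok


def _missing_cells(g: pd.DataFrame, design: dict, reps: int) -> list:
    counts = g.groupby(["block", "stimulus"], sort=False).size()
    missing = []
    for b, stimuli in design.items():
        for s in stimuli:
            have = int(counts.get((b, s), 0))
            if have != reps:
                missing.append((b, s, have))
    return missing


def _round_half_even(total: int, n: int) -> int:
    """Round total/n to the nearest integer, ties to even, exactly."""
    q, r = divmod(total, n)
    if 2 * r < n:
        return q
    if 2 * r > n:
        return q + 1
    return q if q % 2 == 0 else q + 1


def _round_half_up(total: int, n: int) -> int:
    q, r = divmod(total, n)
    return q + 1 if 2 * r >= n else q


def _round_mean(total: int, n: int, rounding: Rounding) -> int:
    if rounding == "half-even":
        return _round_half_even(total, n)
    if rounding == "half-up":
        return _round_half_up(total, n)
    raise ValueError("rounding must be 'half-even' or 'half-up'")


def rounded_mean_input(
    ratings: Sequence[int], rounding: Rounding = "half-even"
) -> int:
    """Mean of the repeated ratings, rounded to the nearest integer.

    This is the "input" category: the rater's settled judgment of the
    stimulus within the block.  Exact integer arithmetic; ties round half to
    even by default (the convention of R's ``round``, under which the
    original analysis ran), switchable to half-up.  A mean of five integers
    can never land on a half-integer, so the tie rule only bites in
    leave-one-out mode (means of four).
    """
    ratings = list(ratings)
    if not ratings:
        raise ValidationError("cannot take the mean of zero ratings")
    return _round_mean(int(sum(ratings)), len(ratings), rounding)


def loo_inputs(
    ratings: Sequence[int], rounding: Rounding = "half-even"
) -> list[int]:
    """Leave-one-out inputs: element i is the rounded mean of the others.

    Removes the self-dependence of the plug-in construction (the plain mean
    contains the rating it is paired with, which inflates MI).
    """
    ratings = [int(r) for r in ratings]
    if len(ratings) < 2:
        raise ValidationError("leave-one-out needs at least 2 repetitions")
    total = sum(ratings)
    n = len(ratings) - 1
    return [_round_mean(total - r, n, rounding) for r in ratings]


def _block_pairs(
    block_frame: pd.DataFrame, mode: Mode, rounding: Rounding
) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    for _, g in block_frame.groupby("stimulus", sort=False):
        ratings = g.sort_values("repetition")["rating"].tolist()
        if mode == "plugin":
            x = rounded_mean_input(ratings, rounding)
            pairs.extend((x, y) for y in ratings)
        elif mode == "loo":
            xs = loo_inputs(ratings, rounding)
            pairs.extend(zip(xs, ratings))
        else:
            raise ValueError("mode must be 'plugin' or 'loo'")
    return pairs


def participant_block_table(
    dataset: RatingDataset,
    participant,
    block,
    mode: Mode = "plugin",
    rounding: Rounding = "half-even",
) -> ContingencyTable:
    """The (input, output) contingency table for one participant and block.

    One pair per individual rating; the table spans the full declared scale.
    Raises on incomplete blocks, listing the missing cells.
    """
    df = dataset.frame
    g = df[(df["participant"] == participant) & (df["block"] == block)]
    if len(g) == 0:
        raise ValidationError(
            f"no records for participant {participant!r}, block {block!r}"
        )
    stimuli = dataset.design_summary()[block]
    missing = _missing_cells(g, {block: stimuli}, dataset.repetitions)
    if missing:
        raise ValidationError(
            f"incomplete block {block!r} for participant {participant!r}; "
            f"missing (block, stimulus, n_found): {missing}"
        )
    pairs = _block_pairs(g, mode, rounding)
    return contingency_from_pairs(pairs, dataset.scale)


def participant_block_mi(
    dataset: RatingDataset,
    participant,
    block,
    mode: Mode = "plugin",
    rounding: Rounding = "half-even",
    bias_correction: bool = False,
) -> float:
    """Mutual information (bits) between input and output for one block.

    ``bias_correction=True`` applies the Miller–Madow first-order
    correction (a small-sample diagnostic; the headline analysis is the
    plug-in estimate).
    """
    table = participant_block_table(dataset, participant, block, mode,
                                    rounding)
    if bias_correction:
        return miller_madow_bits(table)
    return mutual_information_bits(table)


@dataclass(frozen=True)
class MICurvePoint:
    """One point of the MI-vs-source-entropy curve.

    Source entropy is log2(number of distinct stimuli in the block): every
    stimulus is presented equally often, so the source is uniform.
    mi_mean/mi_sd summarize participant-level MI values (population SD, as
    error-bar spread), or hold a single pooled estimate with sd 0.
    """

    n_stimuli: int
    source_entropy_bits: float
    mi_mean_bits: float
    mi_sd_bits: float
    n_participants: int

    def __post_init__(self) -> None:
        if self.source_entropy_bits != math.log2(self.n_stimuli):
            raise ValidationError(
                "source_entropy_bits must equal log2(n_stimuli)"
            )
        if self.mi_mean_bits < 0 or self.mi_sd_bits < 0:
            raise ValidationError("MI summaries must be non-negative")


def aggregate_curve(
    dataset: RatingDataset,
    mode: Mode = "plugin",
    rounding: Rounding = "half-even",
    pooled: bool = False,
    bias_correction: bool = False,
) -> list[MICurvePoint]:
    """The MI-vs-source-entropy curve, one point per distinct block size.

    Default: MI is computed per participant per block and averaged across
    participants, with the standard deviation as spread.  ``pooled=True``
    instead pools all participants' (input, output) pairs per block size
    into one table and reports a single MI (sd 0); the two conventions
    answer slightly different questions and are both exposed.  Blocks that
    share a size are aggregated together.  Incomplete participants are
    dropped with a warning.
    """
    participants = dataset.complete_participants()
    if not participants:
        raise ValidationError("no complete participants in dataset")
    design = dataset.design_summary()
    sizes: dict[int, list] = {}
    for b, stimuli in design.items():
        sizes.setdefault(len(stimuli), []).append(b)

    points = []
    df = dataset.frame
    for k in sorted(sizes):
        blocks = sizes[k]
        if pooled:
            pairs: list[tuple[int, int]] = []
            for b in blocks:
                for p in participants:
                    g = df[(df["participant"] == p) & (df["block"] == b)]
                    pairs.extend(_block_pairs(g, mode, rounding))
            table = contingency_from_pairs(pairs, dataset.scale)
            mi = (miller_madow_bits(table) if bias_correction
                  else mutual_information_bits(table))
            points.append(MICurvePoint(k, math.log2(k), mi, 0.0,
                                       len(participants)))
        else:
            values = [
                participant_block_mi(dataset, p, b, mode, rounding,
                                     bias_correction)
                for b in blocks for p in participants
            ]
            values = np.asarray(values)
            points.append(MICurvePoint(
                k, math.log2(k), float(values.mean()),
                float(values.std()), len(participants)))
    return points


@dataclass(frozen=True)
class CapacityEstimate:
    """Fitted capacity asymptote with its fit diagnostics.

    The asymptote is fit-form dependent: it is the C of a saturating
    exponential, not a model-free quantity.
    """

    asymptote_bits: float
    tau_bits: float
    rss: float
    method: str
    n_points: int


def _saturating_exponential(h, c, tau):
    return c * (1.0 - np.exp(-h / tau))


def fit_capacity(
    curve: Sequence[MICurvePoint],
    include_origin: bool = True,
) -> CapacityEstimate:
    """Least-squares fit of I(H) = C (1 - exp(-H/tau)); C is the capacity.

    By default the origin (0, 0) is included as a data point: a source with
    no information can transmit none.  The functional form is a convention
    — the data determine a plateau level, not a unique parametric curve —
    so the estimate is labeled with its method.
    """
    h = [pt.source_entropy_bits for pt in curve]
    i = [pt.mi_mean_bits for pt in curve]
    if include_origin:
        h = [0.0] + h
        i = [0.0] + i
    h = np.asarray(h, dtype=float)
    i = np.asarray(i, dtype=float)
    if h.size < 3:
        raise ValidationError(
            f"need at least 3 points to fit 2 parameters, got {h.size}"
        )
    if np.allclose(i, 0.0):
        return CapacityEstimate(0.0, float("nan"), 0.0,
                                "saturating-exponential", h.size)
    best = None
    imax = float(i.max())
    for c0, tau0 in [(imax, 1.0), (imax, 0.3), (imax, 3.0), (2.0, 1.5)]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _saturating_exponential, h, i, p0=[c0, tau0],
                    maxfev=20000)
        except RuntimeError:
            continue
        rss = float(((i - _saturating_exponential(h, *popt)) ** 2).sum())
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise ValidationError(
            "capacity fit did not converge from any starting point; "
            f"H={h.tolist()}, I={i.tolist()}"
        )
    (c, tau), rss = best
    return CapacityEstimate(float(c), float(tau), rss,
                            "saturating-exponential", h.size)


def sevenpoint_to_tenpoint(x: float) -> float:
    """Linearly map a 7-point-scale value onto the 10-point scale.

    1 -> 1 and 7 -> 10; used to place reference (crowd-sourced) mean ratings
    on the scale the analysis uses.
    """
    if not 1.0 <= x <= 7.0:
        raise ValidationError(f"value {x!r} outside the 7-point scale [1, 7]")
    return 1.0 + 9.0 * (x - 1.0) / 6.0


def pearson_validate(
    means_a: Sequence[float], means_b: Sequence[float]
) -> float:
    """Pearson r between two sets of per-stimulus mean ratings.

    Used to check that the sample's mean ratings track the reference means
    the stimuli were selected by.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValidationError("need equal-length sequences of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("zero variance: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def curve_to_frame(curve: Sequence[MICurvePoint]) -> pd.DataFrame:
    """Curve points as a DataFrame in the output CSV dialect."""
    return pd.DataFrame(
        {
            "n_stimuli": [p.n_stimuli for p in curve],
            "source_entropy_bits": [p.source_entropy_bits for p in curve],
            "mi_mean_bits": [p.mi_mean_bits for p in curve],
            "mi_sd_bits": [p.mi_sd_bits for p in curve],
            "n_participants": [p.n_participants for p in curve],
        }
    )
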