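"""Synthetic rater-channel datasets with the study's statistical structure.

The generator reproduces the experimental design the analysis assumes:
50 participants, four blocks containing 3, 4, 6 and 10 distinct stimuli,
five repetitions of each stimulus per block (15/20/30/50 trials per block),
ratings on a 1–10 scale, and per-stimulus true means uniformly spaced
between the two anchor stimuli at 2.7 and 9.8 — both anchors present in
every block so the rated range stays constant across blocks.

A rater is modeled as a Gaussian channel: the response to a stimulus with
true mean mu is mu + noise (SD sigma), rounded to the nearest integer and
clamped to the scale.  This is the simplest channel with a single
capacity-controlling parameter; the default sigma is calibrated so that a
full simulated study, analyzed by the pipeline, yields a fitted capacity
near 2.3 bits.  Real raters are certainly not homoscedastic Gaussians —
see the package's methods note for what the simulations do and do not show.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .infotheory import ValidationError, _mi_from_joint
from .pipeline import RatingDataset

__all__ = [
    "DEFAULT_SIGMA",
    "ExperimentDesign",
    "ChannelSpec",
    "confusion_matrix",
    "simulate_dataset",
    "theoretical_block_mi",
    "calibrate_sigma",
]

# Rater noise SD for which the default simulated study, run through the
# plug-in pipeline and the saturating-exponential fit, measures a capacity
# of ~2.3 bits (mean fitted asymptote 2.30 over independent seeds).
DEFAULT_SIGMA = 0.48


@dataclass(frozen=True)
class ExperimentDesign:
    """Block structure of the rating experiment.

    Per-block stimulus means are uniformly spaced between the two anchors
    (rounded to one decimal, the granularity of the anchor values), with
    both anchors present in every block.
    """

    block_sizes: tuple[int, ...] = (3, 4, 6, 10)
    repetitions: int = 5
    scale_min: int = 1
    scale_max: int = 10
    anchors: tuple[float, float] = (2.7, 9.8)
    participants: int = 50

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
        if any(k < 2 for k in self.block_sizes):
            raise ValidationError("every block needs at least 2 stimuli "
                                  "(both anchors are always present)")
        if self.repetitions < 1 or self.participants < 1:
            raise ValidationError("repetitions and participants must be >= 1")
        lo, hi = self.anchors
        if not (self.scale_min <= lo < hi <= self.scale_max):
            raise ValidationError("anchors must be ordered and within scale")

    def block_means(self, n_stimuli: int) -> np.ndarray:
        """True means for a block: anchors plus uniform spacing between."""
        lo, hi = self.anchors
        return np.round(np.linspace(lo, hi, n_stimuli), 1)

    @property
    def scale(self) -> range:
        return range(self.scale_min, self.scale_max + 1)


@dataclass(frozen=True)
class ChannelSpec:
    """A simulated rater: Gaussian noise, discretized and clamped.

    ``participant_offset_sd`` adds a per-participant shift of all true
    means (individual taste), drawn once per participant; 0 by default.
    """

    sigma: float = DEFAULT_SIGMA
    participant_offset_sd: float = 0.0
    noise: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.participant_offset_sd < 0:
            raise ValidationError("noise SDs must be non-negative")
        if self.noise != "gaussian":
            raise ValidationError(f"unknown noise model {self.noise!r}")


def confusion_matrix(
    channel: ChannelSpec,
    stimulus_means: Sequence[float],
    scale_min: int = 1,
    scale_max: int = 10,
) -> np.ndarray:
    """Exact rating probabilities for each stimulus (rows are stimuli).

    Rating r (interior) is produced when the noisy response falls in
    [r - 0.5, r + 0.5); the Gaussian tails fold into the end categories, so
    rows sum to 1 exactly.  With sigma = 0 each row is a point mass on the
    clamped rounded mean.
    """
    means = np.asarray(stimulus_means, dtype=float)
    if np.any(means < scale_min) or np.any(means > scale_max):
        raise ValidationError("stimulus means must lie within the scale")
    cats = np.arange(scale_min, scale_max + 1)
    if channel.sigma == 0:
        rows = np.zeros((means.size, cats.size))
        idx = np.clip(np.rint(means), scale_min, scale_max).astype(int)
        rows[np.arange(means.size), idx - scale_min] = 1.0
        return rows
    edges = np.concatenate(([-np.inf], cats[:-1] + 0.5, [np.inf]))
    z = (edges[None, :] - means[:, None]) / channel.sigma
    return np.diff(norm.cdf(z), axis=1)


def _no_consecutive_order(
    rng: np.random.Generator, n_stimuli: int, repetitions: int,
    max_tries: int = 100_000,
) -> np.ndarray:
    """A shuffled trial order with no stimulus twice in a row."""
    trials = np.repeat(np.arange(n_stimuli), repetitions)
    for _ in range(max_tries):
        order = rng.permutation(trials)
        if not np.any(order[1:] == order[:-1]):
            return order
    raise RuntimeError("could not draw a no-consecutive-repeat order")


def simulate_dataset(
    design: ExperimentDesign = ExperimentDesign(),
    channel: ChannelSpec = ChannelSpec(),
    seed: int = 0,
) -> RatingDataset:
    """Simulate the full experiment: one rating per trial, all participants.

    Ratings are drawn independently from each stimulus's confusion-matrix
    row.  The trial order within a block is a seeded shuffle redrawn until
    no stimulus appears twice in a row.  The master seed spawns one
    independent substream per participant, so datasets are reproducible and
    participants do not share randomness.
    """
    master = np.random.SeedSequence(seed)
    rows: list[dict] = []
    cats = np.arange(design.scale_min, design.scale_max + 1)
    base_conf = {
        k: confusion_matrix(channel, design.block_means(k),
                            design.scale_min, design.scale_max)
        for k in set(design.block_sizes)
    }
    for p, child in enumerate(master.spawn(design.participants)):
        rng = np.random.default_rng(child)
        offset = (rng.normal(0.0, channel.participant_offset_sd)
                  if channel.participant_offset_sd > 0 else 0.0)
        for b, k in enumerate(design.block_sizes):
            means = design.block_means(k)
            if offset != 0.0:
                shifted = np.clip(means + offset, design.scale_min,
                                  design.scale_max)
                conf = confusion_matrix(channel, shifted,
                                        design.scale_min, design.scale_max)
            else:
                conf = base_conf[k]
            order = _no_consecutive_order(rng, k, design.repetitions)
            rep_counter = dict.fromkeys(range(k), 0)
            for s in order:
                rep_counter[s] += 1
                rating = int(rng.choice(cats, p=conf[s]))
                rows.append({
                    "participant": f"P{p + 1:03d}",
                    "block": f"B{b + 1}",
                    "stimulus": f"B{b + 1}S{s + 1:02d}",
                    "repetition": rep_counter[s],
                    "rating": rating,
                    "true_mean": means[s],
                })
    frame = pd.DataFrame(rows)
    return RatingDataset(frame, design.scale_min, design.scale_max,
                         design.repetitions)


def theoretical_block_mi(
    channel: ChannelSpec,
    stimulus_means: Sequence[float],
    scale_min: int = 1,
    scale_max: int = 10,
) -> float:
    """Channel-level MI of a block under an ideal-observer input, in bits.

    Stimuli are presented uniformly; the input category is idealized as the
    stimulus's *rounded true mean* (stimuli whose means round to the same
    integer are indistinguishable at the input).  This is the analytic
    value the estimation pipeline would approach if the empirical rounded
    mean always recovered the true mean — the ground truth for
    parameter-recovery tests, not a statement about finite samples.
    """
    means = np.asarray(stimulus_means, dtype=float)
    conf = confusion_matrix(channel, means, scale_min, scale_max)
    n_cats = scale_max - scale_min + 1
    inputs = np.clip(np.rint(means), scale_min, scale_max).astype(int)
    joint = np.zeros((n_cats, n_cats))
    for x, row in zip(inputs, conf):
        joint[x - scale_min] += row / means.size
    return _mi_from_joint(joint)


def calibrate_sigma(
    target_bits: float,
    design: ExperimentDesign = ExperimentDesign(),
    bracket: tuple[float, float] = (0.01, 5.0),
) -> float:
    """The sigma at which the largest block's theoretical MI hits a target.

    Solves theoretical_block_mi(sigma) = target_bits for the largest block
    by bracketed root finding.  The theoretical MI decreases monotonically
    in sigma from log2(#distinct rounded means) toward 0, so the solution
    is unique when it exists.  Note this calibrates the *channel-level*
    plateau; the pipeline's finite-sample estimate sits above it (see the
    methods note), which is why DEFAULT_SIGMA is calibrated on the measured
    capacity instead.
    """
    k = max(design.block_sizes)
    means = design.block_means(k)

    def gap(sigma: float) -> float:
        return theoretical_block_mi(
            ChannelSpec(sigma=sigma), means,
            design.scale_min, design.scale_max) - target_bits

    lo, hi = bracket
    if gap(lo) < 0 or gap(hi) > 0:
        raise ValidationError(
            f"target {target_bits} bits not bracketed by sigma in {bracket}"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))
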