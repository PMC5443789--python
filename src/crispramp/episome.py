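"""Episomal plasmid loss kinetics.

An OriP/EBNA1 episome replicates once per cell division but segregates
imperfectly, so without drug selection the per-cell copy number decays
geometrically: N(g) = N0 * (1 - r)^g after g generations, with r a few
percent per generation. Given a qPCR time series of relative copy numbers
the loss rate is recovered by least squares on the log scale (qPCR noise
is multiplicative), with generations = 24 * days / generation_time_hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import DecaySeries


def expected_copies(initial: float, loss_rate: float, generations: float) -> float:
    if not 0 < loss_rate < 1:
        raise ValueError("loss rate must lie in (0,1)")
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return initial * (1.0 - loss_rate) ** generations


@dataclass(frozen=True)
class DecayFit:
    loss_rate_per_generation: float
    initial_copies: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0 < self.loss_rate_per_generation < 1:
            raise ValueError(
                f"fitted loss rate {self.loss_rate_per_generation:.4g} outside (0,1); "
                "the series does not show geometric loss"
            )


def fit_loss_rate(series: DecaySeries) -> DecayFit:
    """Log-linear least squares; rate = 1 - exp(slope). Exact recovery on
    noiseless data. Raises on constant or growing series (rate outside (0,1))."""
    if len(series.timepoints) < 3:
        raise ValueError("need at least 3 timepoints to fit a loss rate")
    if any(c <= 0 for c in series.copy_numbers):
        raise ValueError("copy numbers must be positive")
    gens = np.asarray(series.timepoints) * 24.0 / series.generation_time_hours
    logc = np.log(np.asarray(series.copy_numbers))
    res = stats.linregress(gens, logc)
    rate = 1.0 - float(np.exp(res.slope))
    return DecayFit(
        loss_rate_per_generation=rate,
        initial_copies=float(np.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
    )
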