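"""Initial-velocity estimation from CE-derived ligation time courses.

A defined nicked substrate at known concentration is sampled over time; at
each time point the fraction ligated is the product peak's share of total
reporter fluorescence.  The initial velocity V0 is the slope of a linear
fit to the early, approximately linear phase of the reaction (points at or
below a conversion ceiling, 20% by default) multiplied by the substrate
concentration.  Replicates are summarized as mean +/- sample SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trace_analysis import PoolYieldTable


@dataclass
class TimeCourse:
    times: np.ndarray  # seconds, strictly increasing
    fraction: np.ndarray  # fraction ligated in [0, 1]
    substrate_conc: float  # nM
    replicate: str = "r1"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.fraction = np.asarray(self.fraction, float)
        if len(self.times) != len(self.fraction):
            raise ValueError("times and fractions differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.substrate_conc <= 0:
            raise ValueError("substrate concentration must be positive")


@dataclass
class V0Result:
    v0: float  # nM / s
    intercept: float  # fraction units
    points_used: int
    r_squared: float
    replicate: str = "r1"


def fraction_ligated(table: PoolYieldTable, product: str) -> float:
    """Product share of total called reporter fluorescence at one time point.

    ``product`` is the species name in the yield table (e.g. ``"C/pA"``).
    Single-substrate reactions have one expected product; a missing product
    peak reads as zero conversion.
    """
    return table.fraction(product)


def fit_initial_velocity(tc: TimeCourse, max_fraction: float = 0.20) -> V0Result:
    """Least-squares line through the early qualifying phase of a time course.

    Qualifying points are the leading run with fraction <= ``max_fraction``
    (the first disqualifying point ends the run).  An implicit (0, 0)
    anchor joins the fit, since the reaction starts with no product.
    V0 = slope x substrate concentration.
    """
    qualify = tc.fraction <= max_fraction
    n_prefix = int(np.argmin(qualify)) if not qualify.all() else len(qualify)
    if n_prefix < 3:
        raise ValueError(
            f"only {n_prefix} time points at or below {max_fraction:.0%} conversion; "
            "initial-velocity fitting needs >= 3 — sample earlier time points"
        )
    t = np.concatenate([[0.0], tc.times[:n_prefix]])
    f = np.concatenate([[0.0], tc.fraction[:n_prefix]])
    slope, intercept = np.polyfit(t, f, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return V0Result(
        v0=float(slope * tc.substrate_conc),
        intercept=float(intercept),
        points_used=n_prefix,
        r_squared=r2,
        replicate=tc.replicate,
    )


@dataclass
class ReplicateSummary:
    mean_v0: float
    sd_v0: float  # NaN when only one replicate
    n: int


def summarize_replicates(results: Sequence[V0Result]) -> ReplicateSummary:
    """Arithmetic mean and sample SD of V0 across replicate fits."""
    if not results:
        raise ValueError("no replicate results to summarize")
    v = np.array([r.v0 for r in results], float)
    sd = float(v.std(ddof=1)) if len(v) >= 2 else math.nan
    return ReplicateSummary(mean_v0=float(v.mean()), sd_v0=sd, n=len(v))
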