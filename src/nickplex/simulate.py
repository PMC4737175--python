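"""Synthetic CE electropherograms of multiplexed nick-ligation pools.

Emulates fragment-analyzer output for a ligated substrate pool: Gaussian
peaks on a noisy baseline in a FAM reporter channel, a co-injected size
ladder in a second channel, the length-dependent fast mobility of short
FAM-labeled fragments, unreacted downstream probes, ligation products, and
5'-adenylylated (AppN) abortive intermediates including their two
characteristic coelutions (AppA with pG, AppC with pT).

Scenario tables (``tth_like``, ``t4_like``) are qualitative emulations of
published fidelity patterns, intended for testing the analysis pipeline;
they are not ground-truth biochemistry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .panel import (
    ADENYLYL_SHIFT_NT,
    BASES,
    DM,
    DOUBLE,
    UM,
    WC,
    PanelDesign,
    SubstratePool,
    complement,
    product_length,
)

SCENARIOS = ("perfect_fidelity", "tth_like", "t4_like", "uniform", "custom")

# Relative single-mismatch ligation efficiencies for the Tth-like scenario:
# upstream tolerance restricted to the G:T / T:G wobbles, downstream
# tolerance concentrated on pT:T, pT:G, pA:C, pC:A with a lesser tier.
_TTH_UP = {"G:T": 0.10, "T:G": 0.25}
_TTH_DOWN = {
    "pT:T": 0.50, "pT:G": 0.45, "pA:C": 0.40, "pC:A": 0.40,
    "pG:T": 0.08, "pA:A": 0.06, "pG:A": 0.05, "pC:C": 0.04, "pC:T": 0.02,
}

# T4-like: nearly all downstream and most upstream mismatches ligate.
_T4_UP = {
    f"{p}:{s}": (0.4 if p in "AG" and s in "AG" else 0.7)
    for p in BASES for s in BASES if s != complement(p)
}
_T4_DOWN = {
    f"p{p}:{s}": (0.6 if p in "AG" and s in "AG" else 0.9)
    for p in BASES for s in BASES if s != complement(p)
}


@dataclass(frozen=True)
class TrueYieldProfile:
    """Ground-truth reaction outcome for one substrate pool.

    ``product_fraction[(u, d)]`` is the fraction of the pD downstream probe
    converted to the U/pD ligation product; ``adenylylated_fraction[d]`` the
    fraction converted to the AppD abortive intermediate.  The remainder of
    each downstream probe is unreacted.  Upstream probes are unlabeled and
    carry no signal, so conservation is tracked per downstream probe.
    """

    pool: str
    product_fraction: Mapping[tuple[str, str], float]
    adenylylated_fraction: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BASES}
    )

    def __post_init__(self):
        for f in list(self.product_fraction.values()) + list(
            self.adenylylated_fraction.values()
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")
        for d in BASES:
            total = self.reacted_fraction(d)
            if total > 1.0 + 1e-9:
                raise ValueError(
                    f"pool {self.pool}: downstream probe p{d} over-consumed "
                    f"(reacted fraction {total:.3f} > 1)"
                )

    def reacted_fraction(self, down: str) -> float:
        return (
            sum(self.product_fraction.get((u, down), 0.0) for u in BASES)
            + self.adenylylated_fraction.get(down, 0.0)
        )

    def unreacted_fraction(self, down: str) -> float:
        return 1.0 - self.reacted_fraction(down)


@dataclass(frozen=True)
class MobilityModel:
    """Apparent-size model for FAM-labeled fragments.

    Short dye-labeled fragments run fast relative to the (differently
    labeled) size standard, so their apparent size underestimates the true
    length; the effect decays with length.  Shrinkage in apparent-nt units:
    ``amplitude * exp(-L / length_scale) + asymptote``.
    """

    amplitude: float = 8.0
    length_scale: float = 25.0
    asymptote: float = 1.0

    def __post_init__(self):
        if self.amplitude < 0 or self.asymptote < 0 or self.length_scale <= 0:
            raise ValueError("mobility parameters must be non-negative, scale positive")

    def shrinkage(self, true_length):
        return self.amplitude * np.exp(-np.asarray(true_length, float) / self.length_scale) \
            + self.asymptote


def apparent_size(model: MobilityModel, true_length):
    """Apparent (ladder-relative) size of a FAM-labeled fragment.

    Strictly increasing in true length; never exceeds the true length.
    """
    arr = np.asarray(true_length, float)
    if np.any(arr < 1):
        raise ValueError("true_length must be >= 1")
    out = arr - model.shrinkage(arr)
    return float(out) if np.isscalar(true_length) else out


@dataclass(frozen=True)
class TraceSpec:
    """Sampling and signal parameters for synthetic electropherograms."""

    n_samples: int = 5600
    peak_width: float = 0.35  # Gaussian SD, apparent-nt units
    noise_sd: float = 30.0  # baseline noise SD, fluorescence units
    amplitude: float = 175000.0  # integrated area per unit amount
    ladder_sizes: tuple[float, ...] = (15, 20, 25, 35, 50, 62, 80, 110, 120)
    ladder_amplitude: float = 60000.0
    seed: int = 0

    def __post_init__(self):
        if self.peak_width <= 0:
            raise ValueError("peak width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if list(self.ladder_sizes) != sorted(set(self.ladder_sizes)):
            raise ValueError("ladder sizes must be strictly increasing")

    def scan_of_size(self, size):
        """Instrument mapping from apparent size to scan position.

        Mildly nonlinear, as real elution-time axes are.
        """
        s = np.asarray(size, float)
        return 200.0 + 40.0 * s + 0.02 * s**2

    def scan_sigma(self, size: float) -> float:
        # constant width in apparent-nt, converted via the local axis slope
        return self.peak_width * (40.0 + 0.04 * size)


@dataclass
class Electropherogram:
    """Two-channel sampled trace: FAM reporter + size-standard channel."""

    scan: np.ndarray
    reporter: np.ndarray
    standard: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.scan) == len(self.reporter) == len(self.standard)):
            raise ValueError("channel lengths differ")

    @property
    def pool(self) -> str | None:
        return self.metadata.get("pool")


# ---------------------------------------------------------------------------
# Yield-profile construction


def _scenario_profile(
    pool: SubstratePool,
    e_up: Mapping[str, float],
    e_down: Mapping[str, float],
    intensity: float,
    app_fraction: float,
) -> TrueYieldProfile:
    """Build one pool's profile from per-pair mismatch efficiency tables.

    WC pairs have efficiency 1; substrates mismatched on both sides do not
    ligate.  Per downstream probe, product fractions are capped so that
    products plus the adenylylated fraction never exceed the probe amount.
    """
    fractions: dict[tuple[str, str], float] = {}
    for sub in pool.substrates:
        cat = sub.category
        if cat == WC:
            eff = 1.0
        elif cat == UM:
            eff = e_up.get(sub.upstream_pair, 0.0)
        elif cat == DM:
            eff = e_down.get(sub.downstream_pair, 0.0)
        else:  # DOUBLE
            eff = 0.0
        if eff > 0:
            key = (sub.upstream.junction_base, sub.downstream.junction_base)
            fractions[key] = intensity * eff

    app = {b: (app_fraction if any(k[1] == b for k in fractions) else 0.0) for b in BASES}
    for d in BASES:
        total = sum(v for (u, dd), v in fractions.items() if dd == d)
        cap = 1.0 - app[d]
        if total > cap:
            scale = cap / total
            for k in list(fractions):
                if k[1] == d:
                    fractions[k] *= scale
    return TrueYieldProfile(pool.label, fractions, app)


def make_yield_profile(
    scenario: str,
    panel: PanelDesign,
    intensity: float = 0.6,
    seed: int = 0,
    custom: Mapping[str, TrueYieldProfile] | None = None,
    app_fraction: float = 0.05,
) -> dict[str, TrueYieldProfile]:
    """Ground-truth yield profiles for every pool under a named scenario.

    ``intensity`` scales the extent of reaction (the WC product fraction in
    the absence of competition).  ``seed`` is reserved for scenario
    stochasticity; the built-in tables are deterministic.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if not 0.0 <= intensity <= 1.0:
        raise ValueError("intensity must be in [0, 1]")
    if not 0.0 <= app_fraction <= 1.0:
        raise ValueError("app_fraction must be in [0, 1]")

    if scenario == "custom":
        if custom is None:
            raise ValueError("custom scenario requires a profile table")
        if set(custom) != set(panel.pools):
            raise ValueError("custom profiles must cover exactly the panel's pools")
        return dict(custom)  # validated by TrueYieldProfile.__post_init__

    profiles = {}
    for label, pool in panel.pools.items():
        if scenario == "perfect_fidelity":
            wc = next(s for s in pool.substrates if s.category == WC)
            key = (wc.upstream.junction_base, wc.downstream.junction_base)
            profiles[label] = TrueYieldProfile(label, {key: intensity})
        elif scenario == "uniform":
            fr = {(u, d): intensity / 4.0 for u in BASES for d in BASES}
            profiles[label] = TrueYieldProfile(label, fr)
        elif scenario == "tth_like":
            profiles[label] = _scenario_profile(pool, _TTH_UP, _TTH_DOWN,
                                                intensity, app_fraction)
        else:  # t4_like
            profiles[label] = _scenario_profile(pool, _T4_UP, _T4_DOWN,
                                                intensity, app_fraction)
    return profiles


# ---------------------------------------------------------------------------
# Trace synthesis


def species_true_sizes(panel: PanelDesign) -> dict[str, float]:
    """True (or true-equivalent) sizes of every possible reporter species."""
    sizes: dict[str, float] = {}
    for d in BASES:
        L = panel.code.downstream_lengths[d]
        sizes[f"p{d}"] = L
        sizes[f"App{d}"] = L + ADENYLYL_SHIFT_NT
    for u in BASES:
        for d in BASES:
            sizes[f"{u}/p{d}"] = product_length(panel.code, u, d)
    return sizes


def _species_amounts(
    panel: PanelDesign, profile: TrueYieldProfile
) -> dict[str, float]:
    """FAM-bearing species amounts, per unit of each downstream probe."""
    amounts: dict[str, float] = {}
    for d in BASES:
        amounts[f"p{d}"] = profile.unreacted_fraction(d)
        app = profile.adenylylated_fraction.get(d, 0.0)
        if app > 0:
            amounts[f"App{d}"] = app
    for (u, d), fr in profile.product_fraction.items():
        if fr > 0:
            amounts[f"{u}/p{d}"] = fr
    return amounts


def simulate_trace(
    pool: SubstratePool,
    profile: TrueYieldProfile,
    model: MobilityModel,
    spec: TraceSpec,
    panel: PanelDesign,
) -> Electropherogram:
    """Render one pool's reaction outcome as a two-channel electropherogram.

    Every FAM-bearing species (unreacted downstream probes, ligation
    products, AppN intermediates) contributes a Gaussian peak at the scan
    position of its apparent size, with area proportional to its amount
    (equal fluorescence per mole of FAM).  Unlabeled upstream probes and
    splints are invisible.  The standard channel carries the ladder.
    """
    if profile.pool != pool.label:
        raise ValueError(f"profile is for pool {profile.pool}, trace for {pool.label}")
    rng = np.random.default_rng(spec.seed)
    scan = np.arange(spec.n_samples, dtype=float)
    reporter = np.zeros(spec.n_samples)
    standard = np.zeros(spec.n_samples)

    true_sizes = species_true_sizes(panel)
    for name, amount in _species_amounts(panel, profile).items():
        if amount <= 0:
            continue
        app_size = apparent_size(model, true_sizes[name])
        mu = spec.scan_of_size(app_size)
        sigma = spec.scan_sigma(app_size)
        area = amount * spec.amplitude
        reporter += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((scan - mu) / sigma) ** 2
        )

    for size in spec.ladder_sizes:
        mu = spec.scan_of_size(size)  # ladder dye: no FAM mobility offset
        sigma = spec.scan_sigma(size)
        standard += spec.ladder_amplitude / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((scan - mu) / sigma) ** 2
        )

    if spec.noise_sd > 0:
        reporter += rng.normal(0.0, spec.noise_sd, spec.n_samples)
        standard += rng.normal(0.0, spec.noise_sd, spec.n_samples)

    meta = {"pool": pool.label, "seed": spec.seed}
    return Electropherogram(scan, reporter, standard, meta)


def derive_pool_seed(master_seed: int, index: int) -> int:
    """Deterministic per-pool child seed from a master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % 2**31)


def simulate_panel(
    panel: PanelDesign,
    profiles: Mapping[str, TrueYieldProfile],
    model: MobilityModel,
    spec: TraceSpec,
) -> list[Electropherogram]:
    """Simulate all 16 pools in parallel lanes with per-pool derived seeds."""
    missing = set(panel.pools) - set(profiles)
    if missing:
        raise ValueError(f"profiles missing for pools: {sorted(missing)}")
    traces = []
    for i, (label, pool) in enumerate(panel.pools.items()):
        pool_spec = dataclasses.replace(spec, seed=derive_pool_seed(spec.seed, i))
        traces.append(simulate_trace(pool, profiles[label], model, pool_spec, panel))
    return traces


def simulate_timecourse(
    v_true: float,
    substrate_conc: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    plateau: float = 1.0,
    replicate: str = "r1",
):
    """Synthetic single-substrate ligation time course.

    Fraction ligated follows ``min(v_true * t / substrate_conc, plateau)``
    plus seeded Gaussian noise, clipped to [0, 1].  ``v_true`` in nM/s,
    ``substrate_conc`` in nM, times in seconds.
    """
    from .kinetics import TimeCourse

    if v_true < 0:
        raise ValueError("rate must be non-negative")
    t = np.asarray(list(times), float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    f = np.minimum(v_true * t / substrate_conc, plateau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, len(t))
    f = np.clip(f, 0.0, 1.0)
    return TimeCourse(times=t, fraction=f, substrate_conc=substrate_conc,
                      replicate=replicate)
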