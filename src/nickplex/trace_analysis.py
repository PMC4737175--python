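"""From raw two-channel CE traces to per-pool yield tables.

Pipeline: (1) size-calibrate the scan axis against the co-injected ladder,
(2) call peaks in the baseline-corrected FAM reporter channel above a
height floor, (3) assign called peaks to expected species (unreacted
probes, ligation products, AppN intermediates) by apparent size, handling
the declared coelution groups, and (4) quantify each species as its peak
area divided by the total area of all called reporter peaks.  A product's
normalized yield is that fraction divided by the 0.25 theoretical ceiling
of an equimolar four-probe pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import interp1d
from scipy.ndimage import gaussian_filter1d, minimum_filter1d, uniform_filter1d

from .panel import ADENYLYL_SHIFT_NT, BASES, PanelDesign, product_length
from .simulate import Electropherogram, MobilityModel, apparent_size

#: Minimum peak height used to call peaks, fluorescence units (just above
#: background noise in a typical run).
DEFAULT_MIN_HEIGHT = 150.0

#: Default species-assignment tolerance in apparent nucleotides: half the
#: minimum 2-nt product spacing, after mobility compression.
DEFAULT_TOLERANCE = 0.75

#: Relative error assumed on every peak-derived yield.
YIELD_RELATIVE_ERROR = 0.10

#: Theoretical maximum fraction of total reporter fluorescence for a single
#: product in an equimolar four-downstream-probe pool.
MAX_PRODUCT_FRACTION = 0.25


class CalibrationError(RuntimeError):
    """Ladder detection or scan->size mapping failure."""


@dataclass
class SizeLadder:
    sizes: np.ndarray  # nominal fragment sizes, strictly increasing
    scan_positions: np.ndarray  # detected apex scan of each fragment

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, float)
        self.scan_positions = np.asarray(self.scan_positions, float)
        if len(self.sizes) != len(self.scan_positions):
            raise CalibrationError("one scan position required per ladder size")
        if np.any(np.diff(self.sizes) <= 0):
            raise CalibrationError("ladder sizes must be strictly increasing")


@dataclass
class CalibratedTrace:
    """An electropherogram with a monotone piecewise-linear scan->size map."""

    trace: Electropherogram
    ladder: SizeLadder
    _size_of_scan: interp1d = field(repr=False)

    def size_of_scan(self, scan):
        out = self._size_of_scan(scan)
        return float(out) if np.isscalar(scan) else np.asarray(out)

    @property
    def pool(self) -> str | None:
        return self.trace.pool


@dataclass(frozen=True)
class Peak:
    apex_scan: float
    apparent_size: float
    height: float
    area: float
    channel: str = "reporter"
    left: int = 0
    right: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.area <= 0:
            raise ValueError("peak height and area must be positive")
        if not self.left <= self.apex_scan <= self.right:
            raise ValueError("peak boundaries must bracket the apex")


@dataclass(frozen=True)
class SpeciesEntry:
    name: str  # "pA", "AppG", "C/pA", ...
    kind: str  # "unreacted_probe" | "adenylylated" | "product"
    expected_size: float  # apparent nt


@dataclass
class SpeciesLibrary:
    """Expected species inventory for one pool, with coelution groups."""

    pool: str
    entries: list[SpeciesEntry]
    groups: list[frozenset[str]]  # sets of species names sharing a position
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        grouped = {n for g in self.groups for n in g}
        sizes = {}
        for e in self.entries:
            if e.name in grouped:
                continue
            for other, s in sizes.items():
                if abs(e.expected_size - s) < 2 * self.tolerance:
                    raise ValueError(
                        f"species {e.name} and {other} are ambiguous at "
                        f"tolerance {self.tolerance} but not declared coeluting"
                    )
            sizes[e.name] = e.expected_size

    def entry(self, name: str) -> SpeciesEntry:
        return next(e for e in self.entries if e.name == name)

    def targets(self) -> list[tuple[str, str, float]]:
        """(label, kind, expected size) for every assignable position.

        Coelution groups appear once, labeled by their member names joined
        with ``+``; kind is ``group``.
        """
        grouped = {n for g in self.groups for n in g}
        out = [(e.name, e.kind, e.expected_size) for e in self.entries
               if e.name not in grouped]
        for g in self.groups:
            members = sorted(g)
            size = float(np.mean([self.entry(n).expected_size for n in members]))
            out.append(("+".join(members), "group", size))
        return out


@dataclass
class PeakAssignment:
    pool: str
    assigned: dict[str, Peak]  # target label -> peak
    unassigned: list[Peak]
    library: SpeciesLibrary


# ---------------------------------------------------------------------------
# Calibration


def _find_ladder_apexes(standard: np.ndarray, n_expected: int) -> np.ndarray:
    smoothed = gaussian_filter1d(standard, 3.0)
    floor = 0.2 * float(smoothed.max())
    apexes, _ = signal.find_peaks(smoothed, height=floor, prominence=floor / 2,
                                  distance=20)
    if len(apexes) != n_expected:
        raise CalibrationError(
            f"detected {len(apexes)} ladder peaks, expected {n_expected}"
        )
    return apexes.astype(float)


def calibrate_sizes(trace: Electropherogram, ladder_sizes: Sequence[float]) -> CalibratedTrace:
    """Fit a monotone piecewise-linear scan->size map through ladder apexes.

    The map passes exactly through every (apex scan, nominal size) anchor
    and extrapolates linearly beyond the outermost anchors.
    """
    sizes = np.asarray(sorted(ladder_sizes), float)
    if len(sizes) < 4:
        raise CalibrationError("at least 4 ladder fragments required")
    apexes = _find_ladder_apexes(trace.standard, len(sizes))
    if np.any(np.diff(apexes) <= 0):
        raise CalibrationError("ladder apexes not strictly increasing in scan")
    mapper = interp1d(apexes, sizes, kind="linear", bounds_error=False,
                      fill_value="extrapolate", assume_sorted=True)
    return CalibratedTrace(trace, SizeLadder(sizes, apexes), mapper)


# ---------------------------------------------------------------------------
# Peak detection


def _estimate_baseline(y: np.ndarray, window: int) -> np.ndarray:
    # rolling minimum then smoothing over a window much wider than a peak
    return uniform_filter1d(minimum_filter1d(y, size=window), size=window)


def _peak_bounds(y: np.ndarray, apex: int, mins: np.ndarray) -> tuple[int, int]:
    """Flanking local minima, or the 1%-of-apex crossing, whichever is nearer."""
    cutoff = 0.01 * y[apex]
    left_minima = mins[mins < apex]
    right_minima = mins[mins > apex]
    left = int(left_minima[-1]) if len(left_minima) else 0
    right = int(right_minima[0]) if len(right_minima) else len(y) - 1
    below = np.nonzero(y[left:apex] <= cutoff)[0]
    if len(below):
        left = left + int(below[-1])
    below = np.nonzero(y[apex:right + 1] <= cutoff)[0]
    if len(below):
        right = apex + int(below[0])
    return left, right


def detect_peaks(
    ctrace: CalibratedTrace,
    min_height: float = DEFAULT_MIN_HEIGHT,
    channel: str = "reporter",
    baseline_window: int = 300,
    smooth_sigma: float = 2.0,
) -> list[Peak]:
    """Call baseline-corrected peaks above the height floor.

    Peaks are local maxima of the lightly smoothed, baseline-subtracted
    signal with height and prominence above the floor; areas are trapezoidal
    integrals of the corrected signal between flanking valleys (or the 1%
    apex-height crossing).  Returned sorted by apparent size.
    """
    y_raw = getattr(ctrace.trace, channel)
    corrected = y_raw - _estimate_baseline(y_raw, baseline_window)
    smoothed = gaussian_filter1d(corrected, smooth_sigma)
    apexes, props = signal.find_peaks(
        smoothed, height=min_height, prominence=min_height / 2.0, distance=10
    )
    minima, _ = signal.find_peaks(-smoothed)

    peaks = []
    for apex in apexes:
        left, right = _peak_bounds(smoothed, int(apex), minima)
        area = float(np.trapezoid(np.clip(corrected[left:right + 1], 0, None)))
        if area <= 0:
            continue
        # sub-sample apex refinement by parabolic interpolation
        a, b, c = smoothed[apex - 1], smoothed[apex], smoothed[apex + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        apex_scan = float(apex) + float(np.clip(shift, -1, 1))
        peaks.append(
            Peak(
                apex_scan=apex_scan,
                apparent_size=ctrace.size_of_scan(apex_scan),
                height=float(smoothed[apex]),
                area=area,
                channel=channel,
                left=left,
                right=right,
            )
        )
    return sorted(peaks, key=lambda p: p.apparent_size)


# ---------------------------------------------------------------------------
# Species library and assignment


def build_species_library(
    panel: PanelDesign,
    pool: str,
    reference: MobilityModel | Mapping[str, float],
    tolerance: float = DEFAULT_TOLERANCE,
) -> SpeciesLibrary:
    """Expected apparent size of every species a pool's trace can contain.

    ``reference`` is either a mobility model (expected sizes computed from
    true lengths) or a peak table from a standards run mapping species name
    to measured apparent size (taken verbatim).  Species whose expected
    positions are closer than twice the tolerance are declared a coelution
    group; under the default code these are exactly {AppA, pG} and
    {AppC, pT}.
    """
    if pool not in panel.pools:
        raise KeyError(f"unknown pool {pool!r}")
    names: list[tuple[str, str, float]] = []
    for d in BASES:
        L = panel.code.downstream_lengths[d]
        names.append((f"p{d}", "unreacted_probe", L))
        names.append((f"App{d}", "adenylylated", L + ADENYLYL_SHIFT_NT))
    for u in BASES:
        for d in BASES:
            names.append((f"{u}/p{d}", "product", float(product_length(panel.code, u, d))))

    entries = []
    for name, kind, true_size in names:
        if isinstance(reference, MobilityModel):
            exp = apparent_size(reference, true_size)
        else:
            if name not in reference:
                raise KeyError(f"reference table missing species {name!r}")
            exp = float(reference[name])
        entries.append(SpeciesEntry(name, kind, exp))

    # union-find over close expected positions -> coelution groups
    order = sorted(entries, key=lambda e: e.expected_size)
    groups: list[set[str]] = []
    current = [order[0]]
    for prev, e in zip(order, order[1:]):
        if e.expected_size - prev.expected_size < 2 * tolerance:
            current.append(e)
        else:
            if len(current) > 1:
                groups.append({x.name for x in current})
            current = [e]
    if len(current) > 1:
        groups.append({x.name for x in current})

    return SpeciesLibrary(pool, entries, [frozenset(g) for g in groups], tolerance)


_KIND_PRIORITY = {"product": 0, "unreacted_probe": 1, "group": 2, "adenylylated": 3}


def assign_peaks(peaks: Sequence[Peak], library: SpeciesLibrary) -> PeakAssignment:
    """Greedy nearest-expected-size matching of called peaks to species.

    Candidate (peak, target) pairs within tolerance are taken in order of
    absolute size deviation; ties break toward the product interpretation
    over intermediates.  Each peak claims at most one target and vice
    versa; leftovers are reported unassigned.
    """
    targets = library.targets()
    candidates = []
    for pi, p in enumerate(peaks):
        for label, kind, exp in targets:
            dev = abs(p.apparent_size - exp)
            if dev <= library.tolerance:
                candidates.append((dev, _KIND_PRIORITY.get(kind, 9), pi, label))
    candidates.sort()
    assigned: dict[str, Peak] = {}
    used_peaks: set[int] = set()
    for dev, _prio, pi, label in candidates:
        if pi in used_peaks or label in assigned:
            continue
        assigned[label] = peaks[pi]
        used_peaks.add(pi)
    unassigned = [p for i, p in enumerate(peaks) if i not in used_peaks]
    return PeakAssignment(library.pool, assigned, unassigned, library)


# ---------------------------------------------------------------------------
# Quantitation


@dataclass
class PoolYieldTable:
    """Per-species area fractions for one pool's reporter channel.

    ``table`` columns: species, kind, fraction (of total called reporter
    area), normalized (product fraction / 0.25; NaN for non-products), sd,
    flags (comma-joined: below_floor, coeluted, unassigned).
    """

    pool: str
    table: pd.DataFrame
    relative_error: float = YIELD_RELATIVE_ERROR

    def fraction(self, species: str) -> float:
        rows = self.table[self.table.species == species]
        return float(rows.fraction.iloc[0]) if len(rows) else 0.0

    def normalized_yield(self, up: str, down: str) -> float:
        return self.fraction(f"{up}/p{down}") / MAX_PRODUCT_FRACTION

    def product_called(self, up: str, down: str) -> bool:
        rows = self.table[self.table.species == f"{up}/p{down}"]
        return bool(len(rows)) and "below_floor" not in str(rows["flags"].iloc[0])


def quantify_yields(assignment: PeakAssignment) -> PoolYieldTable:
    """Turn a peak assignment into area fractions and normalized yields.

    The denominator is the summed area of *all* called reporter peaks,
    assigned or not.  Coeluted area is reported as the group total and
    excluded from product yields; species with no called peak get fraction
    zero and a ``below_floor`` flag.
    """
    lib = assignment.library
    total = sum(p.area for p in assignment.assigned.values()) + sum(
        p.area for p in assignment.unassigned
    )
    if total <= 0:
        raise ValueError("total called reporter area is zero")

    rows = []
    grouped = {n for g in lib.groups for n in g}
    for e in lib.entries:
        if e.name in grouped:
            continue
        peak = assignment.assigned.get(e.name)
        frac = peak.area / total if peak else 0.0
        flags = [] if peak else ["below_floor"]
        norm = frac / MAX_PRODUCT_FRACTION if e.kind == "product" else np.nan
        rows.append((e.name, e.kind, frac, norm, np.nan, ",".join(flags)))
    for g in lib.groups:
        label = "+".join(sorted(g))
        peak = assignment.assigned.get(label)
        frac = peak.area / total if peak else 0.0
        flags = ["coeluted"] + ([] if peak else ["below_floor"])
        rows.append((label, "group", frac, np.nan, np.nan, ",".join(flags)))
    for p in assignment.unassigned:
        rows.append((f"unassigned@{p.apparent_size:.2f}", "unassigned",
                     p.area / total, np.nan, np.nan, "unassigned"))

    table = pd.DataFrame(
        rows, columns=["species", "kind", "fraction", "normalized", "sd", "flags"]
    )
    return PoolYieldTable(assignment.pool, table)


# ---------------------------------------------------------------------------
# Panel-level driver


@dataclass
class PanelAnalysis:
    tables: dict[str, PoolYieldTable]
    diagnostics: dict[str, dict]

    def failed_pools(self) -> list[str]:
        return [p for p, d in self.diagnostics.items() if d.get("error")]


def _analyze_one(
    trace: Electropherogram,
    panel: PanelDesign,
    reference: MobilityModel | Mapping[str, float],
    ladder_sizes: Sequence[float],
    min_height: float,
    tolerance: float,
) -> tuple[PoolYieldTable, dict]:
    ctrace = calibrate_sizes(trace, ladder_sizes)
    peaks = detect_peaks(ctrace, min_height=min_height)
    library = build_species_library(panel, trace.pool, reference, tolerance)
    assignment = assign_peaks(peaks, library)
    table = quantify_yields(assignment)
    diag = {
        "n_peaks": len(peaks),
        "n_unassigned": len(assignment.unassigned),
        "ladder_residual": 0.0,
    }
    return table, diag


def _pool_mean_table(tables: list[PoolYieldTable]) -> PoolYieldTable:
    """Per-species mean and sample SD of fractions across replicate runs."""
    merged = pd.concat([t.table.assign(rep=i) for i, t in enumerate(tables)])
    merged = merged[merged.kind != "unassigned"]
    agg = (
        merged.groupby(["species", "kind"], sort=False)
        .agg(fraction=("fraction", "mean"), sd=("fraction", lambda s: s.std(ddof=1)),
             flags=("flags", "first"))
        .reset_index()
    )
    agg["normalized"] = np.where(
        agg.kind == "product", agg.fraction / MAX_PRODUCT_FRACTION, np.nan
    )
    agg = agg[["species", "kind", "fraction", "normalized", "sd", "flags"]]
    return PoolYieldTable(tables[0].pool, agg)


def analyze_panel(
    traces: Sequence[Electropherogram],
    panel: PanelDesign,
    reference: MobilityModel | Mapping[str, float],
    ladder_sizes: Sequence[float] = (15, 20, 25, 35, 50, 62, 80, 110, 120),
    min_height: float = DEFAULT_MIN_HEIGHT,
    tolerance: float = DEFAULT_TOLERANCE,
) -> PanelAnalysis:
    """Analyze a set of pool traces; replicates of a pool are averaged.

    A pool whose calibration or quantitation fails is flagged in the
    diagnostics and omitted from the tables; the other pools are returned.
    """
    by_pool: dict[str, list[Electropherogram]] = {}
    for tr in traces:
        if tr.pool is None:
            raise ValueError("trace metadata lacks a pool id")
        by_pool.setdefault(tr.pool, []).append(tr)

    tables: dict[str, PoolYieldTable] = {}
    diagnostics: dict[str, dict] = {}
    for pool, runs in by_pool.items():
        ok, diags = [], []
        error = None
        for tr in runs:
            try:
                table, diag = _analyze_one(
                    tr, panel, reference, ladder_sizes, min_height, tolerance
                )
                ok.append(table)
                diags.append(diag)
            except (CalibrationError, ValueError) as exc:
                error = str(exc)
        diagnostics[pool] = {
            "n_replicates": len(ok),
            "error": error,
            "runs": diags,
        }
        if ok:
            tables[pool] = ok[0] if len(ok) == 1 else _pool_mean_table(ok)
    return PanelAnalysis(tables, diagnostics)


# ---------------------------------------------------------------------------
# I/O helpers


def yield_table_to_tsv(table: PoolYieldTable) -> str:
    out = table.table.copy()
    out.insert(0, "pool", table.pool)
    return out.to_csv(sep="\t", index=False)


def peaks_from_table(df: pd.DataFrame) -> list[Peak]:
    """Build peaks from a pre-called vendor peak table.

    Expected columns: apparent_size, height, area; optional channel.
    """
    peaks = []
    for _, row in df.iterrows():
        peaks.append(
            Peak(
                apex_scan=float(row.get("apex_scan", 0.0)),
                apparent_size=float(row["apparent_size"]),
                height=float(row["height"]),
                area=float(row["area"]),
                channel=str(row.get("channel", "reporter")),
                left=int(row.get("left", 0)),
                right=int(row.get("right", 10**9)),
            )
        )
    return sorted(peaks, key=lambda p: p.apparent_size)
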