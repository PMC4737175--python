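"""Design and validation of length-coded multiplexed nick-ligation panels.

A nicked double-stranded substrate consists of an *upstream* probe providing
the 3'-OH at the ligation junction, a 5'-phosphorylated, 3'-FAM-labeled
*downstream* probe, and a complementary *splint* strand spanning the nick.
The junction base of each probe is encoded in the probe's length, so that
every one of the 16 possible ligation products has a unique size and all of
them can be resolved in a single capillary-electrophoresis lane.  Sixteen
splints — one per junction dinucleotide — give 16 pools that together cover
all 4^4 = 256 junction base combinations.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from Bio.SeqUtils import MeltingTemp as _mt

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Categories of a nick substrate, by junction base pairing.
WC, UM, DM, DOUBLE = "WC", "UM", "DM", "DOUBLE"

#: Apparent-size shift of a 5'-adenylylated (AppN) downstream probe relative
#: to the unmodified probe, expressed in true-nucleotide-equivalent units.
#: Constrained by the observed coelutions AppA/pG and AppC/pT, which sit
#: exactly 4 nt apart in the default length code.
ADENYLYL_SHIFT_NT = 4


def complement(base: str) -> str:
    return COMPLEMENT[base]


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _check_base(base: str) -> None:
    if base not in BASES:
        raise ValueError(f"invalid base {base!r}; expected one of {BASES}")


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class LengthCode:
    """Probe-length code mapping each junction base to a unique probe length.

    The 16 pairwise sums (one upstream + one downstream length) are the true
    ligation-product sizes; they must be pairwise distinct and separated by
    at least ``min_separation`` nucleotides so products are resolvable.
    """

    upstream_lengths: Mapping[str, int]
    downstream_lengths: Mapping[str, int]
    min_separation: int = 2

    def __post_init__(self):
        for m in (self.upstream_lengths, self.downstream_lengths):
            for length in m.values():
                if length <= 0:
                    raise ValueError("probe lengths must be positive")

    def product_lengths(self) -> dict[tuple[str, str], int]:
        """All (upstream base, downstream base) -> product length sums."""
        return {
            (u, d): self.upstream_lengths[u] + self.downstream_lengths[d]
            for u in self.upstream_lengths
            for d in self.downstream_lengths
        }

    def is_valid(self) -> bool:
        sums = sorted(self.product_lengths().values())
        gaps = [b - a for a, b in zip(sums, sums[1:])]
        return len(set(sums)) == len(sums) and all(g >= self.min_separation for g in gaps)


@dataclass(frozen=True)
class ProbeSpec:
    side: str  # "upstream" | "downstream"
    junction_base: str
    length: int
    sequence: str  # 5'->3'
    labeled: bool = False  # 3'-FAM, downstream only
    phosphorylated_5p: bool = False  # downstream only

    def __post_init__(self):
        _check_base(self.junction_base)
        if self.side not in ("upstream", "downstream"):
            raise ValueError(f"invalid side {self.side!r}")
        if len(self.sequence) != self.length:
            raise ValueError("sequence length does not match declared length")
        terminal = self.sequence[-1] if self.side == "upstream" else self.sequence[0]
        if terminal != self.junction_base:
            raise ValueError(
                f"{self.side} probe junction terminus {terminal!r} != "
                f"declared junction base {self.junction_base!r}"
            )
        if self.side == "downstream" and not self.labeled:
            raise ValueError("downstream probes carry the 3'-FAM label")

    @property
    def name(self) -> str:
        return self.junction_base if self.side == "upstream" else "p" + self.junction_base


@dataclass(frozen=True)
class SplintSpec:
    """Template strand spanning the nick; stored 5'->3'.

    ``upstream_junction_base`` pairs opposite the upstream probe's 3'
    terminus; ``downstream_junction_base`` pairs opposite the downstream
    probe's 5'-phosphate terminus.  The pool label reads the splint junction
    dinucleotide 3'->5' with the upstream-pairing base first.
    """

    upstream_junction_base: str
    downstream_junction_base: str
    length: int
    sequence: str
    upstream_coverage: int = 20  # splint bases pairing the upstream probe
    downstream_coverage: int = 30

    def __post_init__(self):
        _check_base(self.upstream_junction_base)
        _check_base(self.downstream_junction_base)
        if len(self.sequence) != self.length:
            raise ValueError("splint sequence length mismatch")

    @property
    def label(self) -> str:
        """Junction dinucleotide read 3'->5' (upstream-pairing base first)."""
        return self.upstream_junction_base + self.downstream_junction_base

    def junction_dinucleotide_3to5(self) -> str:
        """Read the junction dinucleotide off the stored sequence, 3'->5'."""
        i = self.downstream_coverage  # index of the upstream-pairing base
        return self.sequence[i] + self.sequence[i - 1]


@dataclass(frozen=True)
class NickSubstrate:
    upstream: ProbeSpec
    downstream: ProbeSpec
    splint: SplintSpec

    @property
    def upstream_pair(self) -> str:
        """Probe:splint pair at the upstream junction, e.g. ``"C:G"``."""
        return f"{self.upstream.junction_base}:{self.splint.upstream_junction_base}"

    @property
    def downstream_pair(self) -> str:
        """Probe:splint pair at the downstream junction, e.g. ``"pA:T"``."""
        return f"p{self.downstream.junction_base}:{self.splint.downstream_junction_base}"

    @property
    def category(self) -> str:
        return classify_substrate(self)


@dataclass(frozen=True)
class SubstratePool:
    """One splint mixed with all four upstream and four downstream probes."""

    splint: SplintSpec
    substrates: tuple[NickSubstrate, ...]

    def __post_init__(self):
        if len(self.substrates) != 16:
            raise ValueError("a substrate pool holds 16 nick substrates (4x4)")

    @property
    def label(self) -> str:
        return self.splint.label

    def category_counts(self) -> dict[str, int]:
        counts = {WC: 0, UM: 0, DM: 0, DOUBLE: 0}
        for sub in self.substrates:
            counts[sub.category] += 1
        return counts


@dataclass(frozen=True)
class Buffer:
    """Ionic conditions used for melting-temperature estimation."""

    monovalent_molar: float = 0.025
    mg_molar: float = 0.010


@dataclass(frozen=True)
class PanelDesign:
    code: LengthCode
    upstream_probes: Mapping[str, ProbeSpec]
    downstream_probes: Mapping[str, ProbeSpec]
    pools: Mapping[str, SubstratePool]  # keyed by splint 3'-NN-5' label
    buffer: Buffer = field(default_factory=Buffer)

    @property
    def probes(self) -> list[ProbeSpec]:
        return list(self.upstream_probes.values()) + list(self.downstream_probes.values())

    def pool_labels(self) -> list[str]:
        return list(self.pools)

    def junction_combinations(self) -> set[tuple[str, str]]:
        return {
            (sub.upstream_pair, sub.downstream_pair)
            for pool in self.pools.values()
            for sub in pool.substrates
        }


# ---------------------------------------------------------------------------
# Operations


def classify_substrate(sub: NickSubstrate) -> str:
    """Classify a nick substrate by the complementarity of its two junction pairs."""
    up_ok = sub.splint.upstream_junction_base == complement(sub.upstream.junction_base)
    down_ok = sub.splint.downstream_junction_base == complement(sub.downstream.junction_base)
    if up_ok and down_ok:
        return WC
    if down_ok:
        return UM
    if up_ok:
        return DM
    return DOUBLE


def product_length(code: LengthCode, up: str, down: str) -> int:
    """True length in nucleotides of the U/pD ligation product."""
    _check_base(up)
    _check_base(down)
    return code.upstream_lengths[up] + code.downstream_lengths[down]


def design_length_code(
    n_upstream: int,
    n_downstream: int,
    min_separation: int,
    upstream_start: int,
    downstream_start: int,
) -> LengthCode:
    """Construct a collision-free length code for arbitrary panel sizes.

    The downstream lengths step by ``min_separation`` and the upstream
    lengths step by ``n_downstream * min_separation``, so every pairwise sum
    is distinct and consecutive sums differ by at least ``min_separation``.
    With (4, 4, 2, 20, 30) this reproduces the default 4x4 code.
    """
    if n_upstream < 1 or n_downstream < 1:
        raise ValueError("probe counts must be >= 1")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    if upstream_start < 1 or downstream_start < 1:
        raise ValueError("start lengths must be positive")
    def label(i: int) -> str:
        # junction-base labels; synthetic labels beyond the 4-base alphabet
        return BASES[i] if i < len(BASES) else f"B{i}"

    up_step = n_downstream * min_separation
    upstream = {label(i): upstream_start + i * up_step for i in range(n_upstream)}
    downstream = {
        label(i): downstream_start + i * min_separation for i in range(n_downstream)
    }
    return LengthCode(upstream, downstream, min_separation)


DEFAULT_CODE = design_length_code(4, 4, 2, 20, 30)

#: Tm targets (degC) for the splint-annealing regions of the default design.
TM_TARGET_UPSTREAM = 53.0
TM_TARGET_DOWNSTREAM = 71.0


def tm_estimate(sequence: str, monovalent: float = 0.025, mg: float = 0.010) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    Uses the unified nearest-neighbor parameter set with a magnesium-aware
    monovalent/divalent salt correction.  ``monovalent`` and ``mg`` are
    molar concentrations.  Strand concentration is fixed at 250 nM per
    strand, the order of magnitude of a probe in an annealed pool.
    """
    if len(sequence) < 8:
        raise ValueError("Tm estimation requires sequences of >= 8 nt")
    if any(b not in BASES for b in sequence):
        raise ValueError(f"non-ACGT symbol in sequence {sequence!r}")
    return float(
        _mt.Tm_NN(
            sequence,
            nn_table=_mt.DNA_NN3,
            Na=monovalent * 1000.0,
            Mg=mg * 1000.0,
            saltcorr=7,
            dnac1=250.0,
            dnac2=250.0,
        )
    )


def _draw_seq(rng: random.Random, n: int, gc: float = 0.45) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices(BASES, weights=w, k=n))


def _draw_core(
    rng: random.Random,
    n: int,
    variants: Callable[[str], Iterable[str]],
    target: float,
    buffer: Buffer,
    window: float = 2.5,
    max_tries: int = 20000,
) -> str:
    """Draw a random core whose four junction-base variants all melt near target."""
    for _ in range(max_tries):
        core = _draw_seq(rng, n)
        tms = [
            tm_estimate(v, buffer.monovalent_molar, buffer.mg_molar)
            for v in variants(core)
        ]
        if all(abs(t - target) <= window for t in tms):
            return core
    raise RuntimeError("could not find a core sequence matching the Tm target")


def make_default_panel(context_seed: int = 0, buffer: Buffer | None = None) -> PanelDesign:
    """Build the default 4x4 panel: 8 probes, 16 splint pools, 256 junctions.

    Upstream probes end 3' in their junction base and are 20/28/36/44 nt for
    A/C/G/T; length increments are TC repeats appended as 5' tails so the 20
    splint-annealing bases nearest the junction are shared.  Downstream
    probes start 5'-p with their junction base, are 30/32/34/36 nt for
    pA/pC/pG/pT, end 3' in TC, and grow by TC repeats at the labeled 3' end.
    Splints are 50 nt, identical away from the junction, and cover the 20
    upstream + 30 downstream junction-proximal bases.  Core sequences are
    drawn pseudo-randomly from ``context_seed``, retargeted so the two
    annealing regions melt near the design targets (~53 and ~71 degC).
    """
    buffer = buffer or Buffer()
    rng = random.Random(context_seed)
    code = DEFAULT_CODE

    # 19 shared bases + junction base = the 20-nt upstream annealing region
    core19 = _draw_core(
        rng, 19, lambda c: (c + b for b in BASES), TM_TARGET_UPSTREAM, buffer
    )
    # junction base + 29 shared bases = the 30-nt downstream annealing
    # region; the last two bases are TC so the shortest (unextended) probe
    # also terminates 3' in TC.
    core29 = _draw_core(
        rng, 27, lambda c: (b + c + "TC" for b in BASES), TM_TARGET_DOWNSTREAM, buffer
    ) + "TC"

    upstream = {}
    for b in BASES:
        n_ext = code.upstream_lengths[b] - 20
        seq = "TC" * (n_ext // 2) + core19 + b
        upstream[b] = ProbeSpec("upstream", b, code.upstream_lengths[b], seq)

    downstream = {}
    for b in BASES:
        n_ext = code.downstream_lengths[b] - 30
        seq = b + core29 + "TC" * (n_ext // 2)
        downstream[b] = ProbeSpec(
            "downstream", b, code.downstream_lengths[b], seq,
            labeled=True, phosphorylated_5p=True,
        )

    pools = {}
    for u_s, d_s in itertools.product(BASES, BASES):
        # top strand of the 50-nt duplex region with a WC-paired junction
        top = core19 + complement(u_s) + complement(d_s) + core29
        splint = SplintSpec(u_s, d_s, 50, revcomp(top))
        subs = tuple(
            NickSubstrate(upstream[u], downstream[d], splint)
            for u in BASES
            for d in BASES
        )
        pools[splint.label] = SubstratePool(splint, subs)

    return PanelDesign(code, upstream, downstream, pools, buffer)


@dataclass
class ValidationReport:
    passed: bool
    product_lengths_distinct: bool
    min_product_gap: int
    pool_category_counts: dict[str, dict[str, int]]
    n_junction_combinations: int
    tm_upstream: dict[str, float]
    tm_downstream: dict[str, float]
    size_collisions: list[str]
    failures: list[str]

    def __str__(self) -> str:
        lines = [
            f"panel validation: {'PASS' if self.passed else 'FAIL'}",
            f"  product lengths distinct: {self.product_lengths_distinct}"
            f" (min gap {self.min_product_gap} nt)",
            f"  junction combinations covered: {self.n_junction_combinations}",
            f"  upstream-region Tm (degC): "
            + ", ".join(f"{k}={v:.1f}" for k, v in self.tm_upstream.items()),
            f"  downstream-region Tm (degC): "
            + ", ".join(f"{k}={v:.1f}" for k, v in self.tm_downstream.items()),
        ]
        for f in self.failures:
            lines.append(f"  FAIL: {f}")
        return "\n".join(lines)


def validate_panel(design: PanelDesign) -> ValidationReport:
    """Check a panel's design arithmetic; failures are reported, not raised."""
    failures: list[str] = []

    sums = sorted(design.code.product_lengths().values())
    distinct = len(set(sums)) == len(sums)
    gaps = [b - a for a, b in zip(sums, sums[1:])]
    min_gap = min(gaps) if gaps else 0
    if not distinct:
        dupes = sorted({s for s in sums if sums.count(s) > 1})
        failures.append(f"duplicate product lengths: {dupes}")
    elif min_gap < design.code.min_separation:
        failures.append(
            f"minimum product-length gap {min_gap} < {design.code.min_separation}"
        )

    counts = {label: pool.category_counts() for label, pool in design.pools.items()}
    for label, c in counts.items():
        if (c[WC], c[UM], c[DM], c[DOUBLE]) != (1, 3, 3, 9):
            failures.append(f"pool {label}: category counts {c} != (1, 3, 3, 9)")

    n_combos = len(design.junction_combinations())
    if n_combos != 256:
        failures.append(f"junction combinations covered: {n_combos} != 256")

    tm_up, tm_down = {}, {}
    for b, probe in design.upstream_probes.items():
        region = probe.sequence[-20:]
        tm_up[b] = tm_estimate(region, design.buffer.monovalent_molar, design.buffer.mg_molar)
    for b, probe in design.downstream_probes.items():
        region = probe.sequence[:30]
        tm_down["p" + b] = tm_estimate(
            region, design.buffer.monovalent_molar, design.buffer.mg_molar
        )

    # true-size collisions between products and unreacted probes / AppN species
    collisions = []
    probe_sizes = {f"p{b}": length for b, length in design.code.downstream_lengths.items()}
    app_sizes = {f"App{b}": length + ADENYLYL_SHIFT_NT for b, length in
                 design.code.downstream_lengths.items()}
    for (u, d), L in design.code.product_lengths().items():
        for name, s in {**probe_sizes, **app_sizes}.items():
            if abs(L - s) < design.code.min_separation:
                collisions.append(f"product {u}/p{d} ({L} nt) collides with {name} ({s} nt)")
    failures.extend(collisions)

    return ValidationReport(
        passed=not failures,
        product_lengths_distinct=distinct,
        min_product_gap=min_gap,
        pool_category_counts=counts,
        n_junction_combinations=n_combos,
        tm_upstream=tm_up,
        tm_downstream=tm_down,
        size_collisions=collisions,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# Serialization


def panel_to_json(design: PanelDesign) -> str:
    doc = {
        "code": {
            "upstream_lengths": dict(design.code.upstream_lengths),
            "downstream_lengths": dict(design.code.downstream_lengths),
            "min_separation": design.code.min_separation,
        },
        "buffer": {
            "monovalent_molar": design.buffer.monovalent_molar,
            "mg_molar": design.buffer.mg_molar,
        },
        "upstream_probes": {b: p.sequence for b, p in design.upstream_probes.items()},
        "downstream_probes": {b: p.sequence for b, p in design.downstream_probes.items()},
        "splints": {
            label: pool.splint.sequence for label, pool in design.pools.items()
        },
    }
    return json.dumps(doc, indent=2)


def panel_from_json(text: str) -> PanelDesign:
    doc = json.loads(text)
    code = LengthCode(
        doc["code"]["upstream_lengths"],
        doc["code"]["downstream_lengths"],
        doc["code"]["min_separation"],
    )
    buffer = Buffer(**doc["buffer"])
    upstream = {
        b: ProbeSpec("upstream", b, len(seq), seq)
        for b, seq in doc["upstream_probes"].items()
    }
    downstream = {
        b: ProbeSpec("downstream", b, len(seq), seq, labeled=True, phosphorylated_5p=True)
        for b, seq in doc["downstream_probes"].items()
    }
    pools = {}
    for label, seq in doc["splints"].items():
        splint = SplintSpec(label[0], label[1], len(seq), seq)
        subs = tuple(
            NickSubstrate(upstream[u], downstream[d], splint)
            for u in BASES
            for d in BASES
        )
        pools[label] = SubstratePool(splint, subs)
    return PanelDesign(code, upstream, downstream, pools, buffer)


def probes_to_fasta(design: PanelDesign) -> str:
    """Probe and splint sequences in FASTA, 5'->3'."""
    records = []
    for p in design.probes:
        tag = "3FAM" if p.labeled else "OH"
        records.append((f"{p.name}_up{p.length}" if p.side == "upstream"
                        else f"{p.name}_down{p.length}_{tag}", p.sequence))
    for label, pool in design.pools.items():
        records.append((f"splint_{label}", pool.splint.sequence))
    return "".join(f">{name}\n{seq}\n" for name, seq in records)
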