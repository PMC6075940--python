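"""Polygenic genomes: 156 binary alleles decoded to 16 neurocomputational parameters.

Each parameter is controlled by its own span of bits (polygenicity, no
pleiotropy).  A parameter's value is obtained by counting the 1-alleles
in its span and indexing a lookup table, so population parameter values
follow a Binomial(k, 1/2) count distribution: intermediate values are
common, extremes rare.  Two parameters are categorical (architecture and
the backpropagation error metric); the rest are continuous with injective
monotone tables spanning calibrated ranges from learning failure to
highly successful learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GENOME_BITS = 156

#: (parameter name, number of controlling bits), in genome order
DEFAULT_SPANS = (
    ("hidden_units", 12),
    ("temperature", 12),
    ("noise", 10),
    ("learning_rate", 12),
    ("phonological_lr", 12),
    ("semantic_lr", 12),
    ("momentum", 8),
    ("weight_variance", 10),
    ("architecture", 8),
    ("learning_algorithm", 4),
    ("response_threshold", 6),
    ("pruning_onset", 10),
    ("pruning_probability", 8),
    ("pruning_threshold", 10),
    ("weight_decay", 12),
    ("sparseness", 10),
)

ARCHITECTURES = ("direct_only", "hidden_only", "both")
ALGORITHMS = ("rmse", "cross_entropy")

#: processing-role taxonomy: what each parameter does to learning
ROLE_TAGS = {
    "hidden_units": "capacity",
    "architecture": "capacity",
    "sparseness": "capacity",
    "pruning_onset": "regressive",
    "pruning_probability": "regressive",
    "pruning_threshold": "regressive",
    "learning_rate": "plasticity",
    "phonological_lr": "plasticity",
    "semantic_lr": "plasticity",
    "momentum": "plasticity",
    "weight_variance": "plasticity",
    "learning_algorithm": "mixed",     # capacity / plasticity
    "temperature": "mixed",            # plasticity / signal
    "noise": "signal",
    "response_threshold": "signal",
    "weight_decay": "signal",
}

#: calibrated (min, max) range per continuous parameter
RANGES = {
    "hidden_units": (6, 500),
    "temperature": (0.0625, 4.0),
    "noise": (0.0, 5.0),
    "learning_rate": (0.005, 0.5),
    "phonological_lr": (0.0, 1.0),
    "semantic_lr": (0.0, 1.0),
    "momentum": (0.0, 0.75),
    "weight_variance": (0.005, 2.25),
    "response_threshold": (0.005, 0.5),
    "pruning_onset": (0, 1000),
    "pruning_probability": (0.0, 1.0),
    "pruning_threshold": (0.1, 1.5),
    "weight_decay": (0.0, 984.3e-7),
    "sparseness": (0.0, 0.7),
}

#: parameters whose range spans an order of magnitude or more get
#: log-spaced tables; the rest are linear
LOG_SPACED = ("hidden_units", "temperature", "learning_rate",
              "weight_variance", "weight_decay")

#: calibrated "adequate" value per parameter, pinned to the midpoint
#: bit-count so that the most common decoded configuration learns the
#: domain successfully ("just enough to succeed and then a little bit
#: more").  Parameters absent here use the plain midpoint of their
#: (linear) table, which already serves as an adequate value.
ADEQUATE = {
    "hidden_units": 50,       # typical for three-layer past-tense learners
    "temperature": 1.0,       # the standard logistic
    "noise": 1.0,             # mild net-input perturbation, survivable
    "learning_rate": 0.15,    # online backprop rate; see docs on calibration
    "weight_variance": 0.25,  # conventional small-random initialisation
    "weight_decay": 1e-6,     # per-update decay that forgets little within a run
}


@dataclass(frozen=True)
class GeneLayout:
    spans: tuple = DEFAULT_SPANS

    def __post_init__(self):
        names = [n for n, _ in self.spans]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in layout")

    @property
    def total_bits(self) -> int:
        return sum(k for _, k in self.spans)

    def offsets(self) -> dict:
        """Parameter name -> (start, stop) bit slice into the genome."""
        out, pos = {}, 0
        for name, k in self.spans:
            out[name] = (pos, pos + k)
            pos += k
        return out


def default_layout() -> GeneLayout:
    return GeneLayout()


@dataclass(frozen=True)
class Genome:
    alleles: tuple

    def __post_init__(self):
        if any(a not in (0, 1) for a in self.alleles):
            raise ValueError("alleles must be 0/1")

    def __len__(self):
        return len(self.alleles)

    def to_string(self) -> str:
        return "".join(str(a) for a in self.alleles)

    @classmethod
    def from_string(cls, s: str) -> "Genome":
        return cls(tuple(int(c) for c in s.strip()))


def _two_piece_log(lo: float, mid: float, hi: float, k: int) -> np.ndarray:
    """Geometric grid from lo to hi passing through mid at count k/2."""
    half = k // 2
    table = np.empty(k + 1)
    table[: half + 1] = np.geomspace(lo, mid, half + 1)
    table[half:] = np.geomspace(mid, hi, k - half + 1)
    return table


def _two_piece_linear(lo: float, mid: float, hi: float, k: int) -> np.ndarray:
    half = k // 2
    table = np.empty(k + 1)
    table[: half + 1] = np.linspace(lo, mid, half + 1)
    table[half:] = np.linspace(mid, hi, k - half + 1)
    return table


def _decay_table(mid: float, hi: float, k: int) -> np.ndarray:
    # weight decay has a zero lower bound: the zero-count entry is 0, the
    # remaining entries rise geometrically through the adequate midpoint
    # to the printed ceiling
    half = k // 2
    table = np.zeros(k + 1)
    table[1: half + 1] = np.geomspace(mid / 100.0, mid, half)
    table[half:] = np.geomspace(mid, hi, k - half + 1)
    return table


@dataclass
class LookupTables:
    """count-of-1s -> value tables, one per parameter."""

    tables: dict = field(default_factory=dict)

    def __getitem__(self, name):
        return self.tables[name]

    def value(self, name: str, count: int):
        return self.tables[name][count]

    def n_distinct(self, name: str) -> int:
        table = self.tables[name]
        if isinstance(table, np.ndarray):
            return len(np.unique(table))
        return len(set(table))

    def to_frame(self):
        import pandas as pd

        rows = [(name, c, v) for name, table in self.tables.items()
                for c, v in enumerate(table)]
        return pd.DataFrame(rows, columns=["parameter", "count", "value"])


def build_default_tables(layout: GeneLayout | None = None) -> LookupTables:
    """Monotone injective tables over the calibrated ranges.

    Each continuous table runs from the printed minimum, through the
    calibrated adequate value at the midpoint bit-count, to the printed
    maximum, so binomially-common genomes decode to configurations that
    can learn while the tails span failure up to highly successful
    learning.  Spacing is geometric for parameters whose range covers at
    least an order of magnitude and linear otherwise.  Hidden-unit
    counts are rounded to integers (the grid stays injective after
    rounding).  The two categorical parameters bin their binomial counts
    so the layered architecture options carry most of the population
    mass: architecture counts 0-2 -> direct only, 3-5 -> hidden layer
    only, 6-8 -> both pathways; error metric counts 0-2 -> rmse,
    3-4 -> cross-entropy.
    """
    layout = layout or default_layout()
    tables = {}
    for name, k in layout.spans:
        if name == "architecture":
            tables[name] = ["direct_only"] * 3 + ["hidden_only"] * 3 + ["both"] * 3
            continue
        if name == "learning_algorithm":
            tables[name] = ["rmse"] * 3 + ["cross_entropy"] * 2
            continue
        lo, hi = RANGES[name]
        if name == "weight_decay":
            table = _decay_table(ADEQUATE[name], hi, k)
        elif name in LOG_SPACED:
            table = _two_piece_log(lo, ADEQUATE[name], hi, k)
        else:
            mid = ADEQUATE.get(name, (lo + hi) / 2.0)
            table = _two_piece_linear(lo, mid, hi, k)
        if name in ("hidden_units", "pruning_onset"):
            table = np.rint(table).astype(np.int64)
        if len(np.unique(table)) != k + 1:
            raise AssertionError(f"{name} table not injective")
        tables[name] = table
    return LookupTables(tables)


@dataclass(frozen=True)
class ParameterSet:
    """The 16 decoded neurocomputational parameters of one simulated child."""

    hidden_units: int
    temperature: float
    noise: float
    learning_rate: float
    phonological_lr: float
    semantic_lr: float
    momentum: float
    weight_variance: float
    architecture: str
    learning_algorithm: str
    response_threshold: float
    pruning_onset: int
    pruning_probability: float
    pruning_threshold: float
    weight_decay: float
    sparseness: float

    role_tags = ROLE_TAGS

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name, _ in DEFAULT_SPANS}

    def validate(self) -> None:
        for name, (lo, hi) in RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"bad architecture {self.architecture!r}")
        if self.learning_algorithm not in ALGORITHMS:
            raise ValueError(f"bad learning algorithm {self.learning_algorithm!r}")


def sample_genome(rng: np.random.Generator, layout: GeneLayout | None = None) -> Genome:
    """Fair-coin alleles at every locus."""
    layout = layout or default_layout()
    return Genome(tuple(int(b) for b in rng.integers(0, 2, size=layout.total_bits)))


def decode(genome: Genome, layout: GeneLayout | None = None,
           tables: LookupTables | None = None) -> ParameterSet:
    """Bit-count each span and look the counts up in the parameter tables."""
    layout = layout or default_layout()
    tables = tables or build_default_tables(layout)
    if len(genome) != layout.total_bits:
        raise ValueError(f"genome has {len(genome)} bits; layout needs {layout.total_bits}")
    values = {}
    for name, (start, stop) in layout.offsets().items():
        count = sum(genome.alleles[start:stop])
        v = tables.value(name, count)
        if isinstance(v, np.generic):
            v = v.item()
        values[name] = v
    ps = ParameterSet(**values)
    ps.validate()
    return ps


def count_unique_configurations(layout: GeneLayout | None = None,
                                tables: LookupTables | None = None) -> int:
    """Number of distinct decodable parameter configurations.

    With no pleiotropy the parameters decode independently, so the count
    is the product over parameters of the number of distinct table values.
    """
    layout = layout or default_layout()
    tables = tables or build_default_tables(layout)
    total = 1
    for name, _ in layout.spans:
        total *= tables.n_distinct(name)
    return total
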