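"""Core data model shared by every pipeline stage.

All coordinates are 1-based inclusive genomic positions, matching GFF3.
BED input is converted on read. Strands are "+" / "-".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")
MOD_TYPES = frozenset({"m6A", "m4C", "modified_base"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-naive: ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    contig_id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"{self.contig_id}: sequence contains invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int, strand: str = "+") -> str:
        """Base at a 1-based position; minus strand returns the complement."""
        if not 1 <= position <= self.length:
            if self.circular:
                position = (position - 1) % self.length + 1
            else:
                raise IndexError(f"position {position} outside {self.contig_id}")
        b = self.sequence[position - 1]
        return b if strand == "+" else b.translate(_COMPLEMENT)


@dataclass(frozen=True)
class ModifiedBase:
    contig_id: str
    position: int
    strand: str
    base: str
    mod_type: str
    nucmod_score: float
    coverage: int = 0
    ipd_ratio: float | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.nucmod_score < 0:
            raise ValueError("nucmod_score must be >= 0")
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"invalid mod_type {self.mod_type!r}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def tsc_position(self) -> int:
        """First base of the start codon: start on +, end on - strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    label: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for _, s, e in self.intervals)

    def contains(self, contig_id: str, position: int) -> bool:
        return any(
            c == contig_id and s <= position <= e for c, s, e in self.intervals
        )


@dataclass
class ExpressionProfile:
    gene_id: str
    raw_count: float
    rpkm: float = 0.0
    r_value: float = 0.0
    tpm: float = 0.0
    category: int | None = None


@dataclass(frozen=True)
class CategoryShift:
    gene_id: str
    category_a: int
    category_b: int

    @property
    def direction(self) -> str:
        if self.category_b > self.category_a:
            return "up"
        if self.category_b < self.category_a:
            return "down"
        return "none"


@dataclass(frozen=True)
class MotifSpec:
    name: str
    iupac: str
    fwd_methyl_offsets: tuple[int, ...]
    rev_methyl_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.iupac)
        for off in (*self.fwd_methyl_offsets, *self.rev_methyl_offsets):
            if not 0 <= off < n:
                raise ValueError(f"{self.name}: methyl offset {off} outside motif")

    @property
    def length(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class MotifSite:
    contig_id: str
    start: int
    end: int
    orientation: str
    motif_name: str
    # (position, strand, expected_base); one entry per methylatable offset
    methylatable_positions: tuple[tuple[int, str, str], ...]


@dataclass(frozen=True)
class MotifStatus:
    site: MotifSite
    status: str  # fully_methylated | partially_methylated | unmethylated
    per_position_scores: tuple[float, ...]


@dataclass
class WindowStat:
    contig_id: str
    start: int
    end: int
    gc_content: float
    gc_skew: float
    mod_count: int
    skew_undefined: bool = False


@dataclass
class CorrelationReport:
    rho: float
    ci_low: float
    ci_high: float
    n_boot: int
    alpha: float
    flagged: bool = False

    @property
    def significant(self) -> bool:
        if self.flagged:
            return False
        return (self.ci_low > 0 and self.ci_high > 0) or (
            self.ci_low < 0 and self.ci_high < 0
        )


@dataclass
class RegionBias:
    label: str
    f_obs: int
    f_exp: float
    z: float
    p: float


@dataclass
class ContingencyResult:
    offset_start: int
    offset_end: int
    a: int
    b: int
    c: int
    d: int
    chi2_p: float
    ld_raw: float
    ld_norm: float  # NaN when any margin is zero
    window: int = 0

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_genes_eligible(self) -> int:
        return self.n

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.ld_norm)


@dataclass
class SweepConfig:
    window_sizes: tuple[int, ...] = tuple(range(27, 91, 5))
    window_step: int = 2
    offset_range: tuple[int, int] = (-350, 100)
    category_counts: tuple[int, ...] = (3, 4, 5, 6)
    score_cutoffs: tuple[float, ...] = (100, 125, 150, 175, 200)
    significance_p: float = 0.006
    fdr_alpha: float = 0.05
    yates_correction: bool = True

    def __post_init__(self) -> None:
        if not (self.window_sizes and self.category_counts and self.score_cutoffs):
            raise ValueError("sweep grid must be non-empty")
        if any(w < 7 for w in self.window_sizes):
            raise ValueError("window sizes must be >= 7")


#: The alternative sweep grid shipped as a named preset.
SWEEP_PRESETS: dict[str, SweepConfig] = {
    "wide": SweepConfig(),
    "narrow": SweepConfig(
        window_sizes=tuple(range(20, 51, 5)),
        category_counts=(4, 5, 6, 7, 8),
        score_cutoffs=(20, 25, 30, 35, 40, 45, 50),
    ),
}


@dataclass
class OffsetSummary:
    offset: int
    hit_count: int
    mean_ld: float
    ld_sign_profile: str  # positive | negative | mixed | none


@dataclass
class SweepResult:
    offsets: list[OffsetSummary]
    n_grid_points: int
    n_windows_tested: int
    n_windows_significant: int
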