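"""Synthetic two-condition datasets with known ground truth.

Generates random genomes with planted recognition motifs, per-condition
modification call sets (canonical sites plus a noisy non-canonical
background), gene models on both strands, and two-condition expression
counts in which a chosen fraction of genes shift category — optionally
coupled to a concordant modification-count change inside a TSC-relative
window, which is the alternative hypothesis the association sweep is
designed to detect.
"""

from __future__ import annotations

import json
import math
import logging
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import io_formats
from .models import GeneModel, GenomeSequence, ModifiedBase, MotifSite, MotifSpec
from .motifs import IUPAC_SETS, parse_motif, scan_motif

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SyntheticScenario:
    genome_length: int = 200_000
    gc: float = 0.45
    n_genes: int = 200
    gene_length_mean: int = 900
    motifs: list[MotifSpec] = dc_field(default_factory=list)
    n_planted_per_motif: int = 30
    canonical_methylation_rate: float = 0.95
    noncanonical_density: float = 2.0  # latent modifiable positions per kbp
    call_rate: float = 0.7  # per-condition chance a latent position is called
    score_model: tuple[float, float] = (150.0, 40.0)
    coverage_model: tuple[float, float] = (60.0, 15.0)
    shift_fraction: float = 0.3
    coupling_offsets: tuple[int, int] = (-80, -20)
    coupling_strength: float = 0.0
    coupling_calls: int = 3
    dispersion: float = 0.3
    iid_background: bool = False  # fully independent background per condition
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc", "canonical_methylation_rate", "call_rate",
                     "shift_fraction", "coupling_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_length < 10 * self.gene_length_mean:
            raise ValueError("genome_length must be >= 10 * gene_length_mean")


def generate_genome(length: int, gc: float, seed: int, contig_id: str = "synth_1",
                    circular: bool = True) -> GenomeSequence:
    """I.i.d. random genome with P(G) = P(C) = gc/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=length, p=p)
    return GenomeSequence(contig_id, "".join(bases), circular=circular)


def plant_motifs(
    genome: GenomeSequence, motif: MotifSpec, n: int, seed: int
) -> tuple[GenomeSequence, list[MotifSite]]:
    """Write n non-overlapping literal motif copies at random positions.

    N positions in the motif are randomised; planting orientation is
    random for non-palindromic motifs. Returns the edited genome and the
    ground-truth sites (recovered by scanning the edited region).
    """
    if n == 0:
        return genome, []
    rng = np.random.default_rng(seed)
    length, mlen = genome.length, motif.length
    occupied = np.zeros(length, dtype=bool)
    seq = list(genome.sequence)
    from .motifs import is_palindromic, iupac_revcomp

    palindromic = is_palindromic(motif.iupac)
    placements: list[tuple[int, str]] = []
    attempts = 0
    while len(placements) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError(f"could not place {n} non-overlapping motif sites")
        start = int(rng.integers(0, length - mlen + 1))
        if occupied[start : start + mlen].any():
            continue
        occupied[start : start + mlen] = True
        orientation = "+" if palindromic else ("+", "-")[int(rng.integers(2))]
        pattern = motif.iupac if orientation == "+" else iupac_revcomp(motif.iupac)
        for i, ch in enumerate(pattern):
            choices = IUPAC_SETS[ch]
            seq[start + i] = choices[int(rng.integers(len(choices)))] \
                if len(choices) > 1 else choices
        placements.append((start, orientation))
    edited = GenomeSequence(genome.contig_id, "".join(seq), circular=genome.circular)
    # recover ground truth sites by scanning: keeps offsets consistent
    all_sites = scan_motif(edited, motif)
    planted_starts = {p + 1 for p, _ in placements}
    truth = [s for s in all_sites if s.start in planted_starts]
    return edited, truth


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, floor: float = 0.0) -> np.ndarray:
    return np.maximum(rng.normal(mean, sd, size=size), floor)


def _latent_background(
    genome: GenomeSequence,
    density_per_kbp: float,
    seed: int,
    score_model: tuple[float, float],
) -> list[tuple[int, str, str, float]]:
    """Fixed set of modifiable background loci with a per-locus score propensity.

    The stable score mean makes high-scoring calls reproducible across
    conditions, so cross-condition repeatability rises with the score
    cutoff instead of falling.
    """
    rng = np.random.default_rng(seed)
    n = rng.poisson(density_per_kbp * genome.length / 1000)
    loci = []
    while len(loci) < n:
        pos = int(rng.integers(1, genome.length + 1))
        strand = "+-"[int(rng.integers(2))]
        base = genome.base_at(pos, strand)
        if base in ("A", "C"):
            propensity = float(rng.normal(*score_model))
            loci.append((pos, strand, base, propensity))
    return loci


def _locus_call_prob(call_rate: float, propensity: float,
                     score_model: tuple[float, float]) -> float:
    """Per-locus call probability, mildly increasing with score propensity.

    Centred on ``call_rate`` so the expected background call count stays
    at density * call_rate; the tilt makes high-scoring loci the
    reproducible ones across conditions.
    """
    mean, sd = score_model
    return float(np.clip(call_rate + 0.15 * (propensity - mean) / sd, 0.05, 1.0))


def generate_methylome(
    genome: GenomeSequence,
    sites: list[MotifSite],
    scenario: SyntheticScenario,
    condition_tag: str,
    seed: int,
) -> list[ModifiedBase]:
    """One condition's modification call set.

    Canonical: each methylatable position of each site is called with
    probability ``canonical_methylation_rate``. Non-canonical: a latent
    set of background loci (fixed per genome seed) is re-sampled per
    condition at ``call_rate``, modelling cross-experiment repeatability;
    with ``iid_background`` the latent set itself is redrawn per
    condition. Scores and coverages come from truncated normal models.
    """
    cond_seed = (seed, zlib.crc32(condition_tag.encode()))
    rng = np.random.default_rng(cond_seed)
    # (position, strand, base, score mean): canonical calls draw i.i.d. from
    # the score model, background calls jitter around their locus propensity
    calls: list[tuple[int, str, str, float]] = []
    for site in sites:
        for pos, strand, base in site.methylatable_positions:
            if rng.random() < scenario.canonical_methylation_rate:
                if base not in ("A", "C"):
                    base = genome.base_at(pos, strand)
                calls.append((pos, strand, base, float("nan")))
    if scenario.iid_background:
        latent_seed = int(np.random.default_rng(cond_seed).integers(2**31))
    else:
        latent_seed = seed
    latent = _latent_background(
        genome, scenario.noncanonical_density, latent_seed, scenario.score_model
    )
    for locus in latent:
        q = _locus_call_prob(scenario.call_rate, locus[3], scenario.score_model)
        if rng.random() < q:
            calls.append(locus)
    mean, sd = scenario.score_model
    score_means = np.array([mean if math.isnan(m) else m for *_, m in calls])
    score_sds = np.array([sd if math.isnan(m) else sd / 8 for *_, m in calls])
    scores = np.maximum(rng.normal(score_means, score_sds), 0.0) \
        if calls else np.empty(0)
    covs = _truncated_normal(rng, *scenario.coverage_model, size=len(calls))
    mods = [
        ModifiedBase(
            contig_id=genome.contig_id,
            position=pos,
            strand=strand,
            base=base,
            mod_type="m6A" if base == "A" else "m4C",
            nucmod_score=float(score),
            coverage=int(cov),
        )
        for (pos, strand, base, _m), score, cov in zip(calls, scores, covs)
    ]
    mods.sort(key=lambda m: (m.position, m.strand))
    return mods


@dataclass
class LinkedDataset:
    """Two-condition bundle plus generator ground truth."""

    genome: GenomeSequence
    genes: list[GeneModel]
    planted_sites: list[MotifSite]
    mods_a: list[ModifiedBase]
    mods_b: list[ModifiedBase]
    counts_a: dict[str, float]
    counts_b: dict[str, float]
    truth: dict


def _place_genes(rng: np.random.Generator, scenario: SyntheticScenario,
                 contig_id: str) -> list[GeneModel]:
    genes = []
    cursor = 500
    for i in range(scenario.n_genes):
        gap = int(rng.integers(400, 700))
        length = max(150, int(rng.normal(scenario.gene_length_mean,
                                         scenario.gene_length_mean / 4)))
        start = cursor + gap
        end = start + length - 1
        if end > scenario.genome_length - 500:
            break
        strand = "+-"[int(rng.integers(2))]
        genes.append(GeneModel(f"gene_{i:04d}", contig_id, start, end, strand))
        cursor = end
    return genes


def generate_linked_dataset(scenario: SyntheticScenario) -> LinkedDataset:
    """Complete two-condition dataset realising the planted coupling.

    A ``shift_fraction`` of genes get their condition-B expression mean
    scaled up or down (category shift); each shifted gene receives, with
    probability ``coupling_strength``, extra same-strand modification
    calls of concordant direction inside the coupling window. Coupling
    edits calls only — gene coordinates never move.
    """
    rng = np.random.default_rng(scenario.seed)
    genome = generate_genome(scenario.genome_length, scenario.gc, scenario.seed)
    planted: list[MotifSite] = []
    for i, motif in enumerate(scenario.motifs):
        genome, sites = plant_motifs(
            genome, motif, scenario.n_planted_per_motif, scenario.seed + 1000 + i
        )
        planted.extend(sites)
    genes = _place_genes(rng, scenario, genome.contig_id)

    # expression: log-normal baseline, gamma-poisson counts
    base_mean = rng.lognormal(mean=4.0, sigma=1.0, size=len(genes))
    shifted = rng.random(len(genes)) < scenario.shift_fraction
    direction = np.where(rng.random(len(genes)) < 0.5, 1, -1) * shifted
    fold = 6.0
    mean_b = base_mean * np.where(direction > 0, fold,
                                  np.where(direction < 0, 1 / fold, 1.0))

    def draw_counts(means: np.ndarray) -> np.ndarray:
        shape = 1.0 / scenario.dispersion
        lam = rng.gamma(shape, means / shape)
        return rng.poisson(lam)

    counts_a = {g.gene_id: float(c) for g, c in zip(genes, draw_counts(base_mean))}
    counts_b = {g.gene_id: float(c) for g, c in zip(genes, draw_counts(mean_b))}

    mods_a = generate_methylome(genome, planted, scenario, "A", scenario.seed)
    mods_b = generate_methylome(genome, planted, scenario, "B", scenario.seed)

    lo, hi = scenario.coupling_offsets
    coupled = np.zeros(len(genes), dtype=bool)
    extra_a: list[ModifiedBase] = []
    extra_b: list[ModifiedBase] = []
    for i, g in enumerate(genes):
        if direction[i] == 0 or rng.random() >= scenario.coupling_strength:
            continue
        coupled[i] = True
        target = extra_b if direction[i] > 0 else extra_a
        n_extra = 1 + int(rng.integers(scenario.coupling_calls))
        for _ in range(n_extra):
            r = int(rng.integers(lo, hi + 1))
            pos = g.tsc_position + r if g.strand == "+" else g.tsc_position - r
            pos = (pos - 1) % genome.length + 1
            base = genome.base_at(pos, g.strand)
            if base not in ("A", "C"):
                base = "A" if rng.random() < 0.5 else "C"  # synthetic call, keep density
            target.append(
                ModifiedBase(
                    contig_id=genome.contig_id,
                    position=pos,
                    strand=g.strand,
                    base=base,
                    mod_type="m6A" if base == "A" else "m4C",
                    nucmod_score=float(_truncated_normal(
                        rng, *scenario.score_model, 1)[0]),
                    coverage=int(_truncated_normal(
                        rng, *scenario.coverage_model, 1)[0]),
                )
            )
    mods_a = sorted(mods_a + extra_a, key=lambda m: (m.position, m.strand))
    mods_b = sorted(mods_b + extra_b, key=lambda m: (m.position, m.strand))

    truth = {
        "coupling_offsets": [lo, hi],
        "coupling_strength": scenario.coupling_strength,
        "genes": {
            g.gene_id: {
                "shift_direction": {1: "up", -1: "down", 0: "none"}[int(direction[i])],
                "coupled": bool(coupled[i]),
                "strand": g.strand,
                "tsc": g.tsc_position,
            }
            for i, g in enumerate(genes)
        },
    }
    return LinkedDataset(
        genome, genes, planted, mods_a, mods_b, counts_a, counts_b, truth
    )


def write_dataset(dataset: LinkedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.gff3",
        "mods_a": outdir / "modifications_A.gff3",
        "mods_b": outdir / "modifications_B.gff3",
        "counts_a": outdir / "counts_A.tsv",
        "counts_b": outdir / "counts_B.tsv",
        "truth": outdir / "truth.json",
    }
    io_formats.write_genome_fasta([dataset.genome], paths["genome"])
    io_formats.write_annotation_gff(dataset.genes, paths["annotation"])
    io_formats.write_modifications_gff(dataset.mods_a, paths["mods_a"])
    io_formats.write_modifications_gff(dataset.mods_b, paths["mods_b"])
    io_formats.write_counts_tsv(dataset.counts_a, paths["counts_a"])
    io_formats.write_counts_tsv(dataset.counts_b, paths["counts_b"])
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1)
    log.info("wrote synthetic dataset to %s", outdir)
    return paths
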