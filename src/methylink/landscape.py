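"""Chromosome-wide landscape statistics.

Sliding-window GC content / GC skew / modified-base density profiles,
Spearman correlation with percentile-bootstrap confidence intervals, and
region-bias Z statistics Z = (F_obs - F_exp) / sqrt(F_exp + 1) with
standard-normal survival-function p-values.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .models import (
    CorrelationReport,
    GeneModel,
    GenomeSequence,
    ModifiedBase,
    RegionBias,
    RegionSet,
    WindowStat,
)

log = logging.getLogger(__name__)


def window_profile(
    genome: GenomeSequence,
    mods: Sequence[ModifiedBase],
    window: int = 8000,
    step: int = 2000,
) -> list[WindowStat]:
    """GC content, GC skew and modification count in sliding windows.

    Windows start every ``step`` bp from position 1. On circular genomes
    the final windows wrap across the origin; on linear genomes they are
    truncated at the end. Calls on both strands are counted by position.
    """
    if window > genome.length:
        raise ValueError("window exceeds genome length")
    if step < 1:
        raise ValueError("step must be >= 1")
    length = genome.length
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    is_g = (seq == b"G").astype(np.int64)
    is_c = (seq == b"C").astype(np.int64)
    mod_hist = np.zeros(length, dtype=np.int64)
    for m in mods:
        if m.contig_id == genome.contig_id and 1 <= m.position <= length:
            mod_hist[m.position - 1] += 1
    if genome.circular:
        is_g = np.concatenate([is_g, is_g[: window - 1]])
        is_c = np.concatenate([is_c, is_c[: window - 1]])
        mod_hist = np.concatenate([mod_hist, mod_hist[: window - 1]])
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    cm = np.concatenate([[0], np.cumsum(mod_hist)])
    out: list[WindowStat] = []
    for start0 in range(0, length, step):
        end0 = min(start0 + window, len(cg) - 1)
        size = end0 - start0
        g = int(cg[end0] - cg[start0])
        c = int(cc[end0] - cc[start0])
        n_mod = int(cm[end0] - cm[start0])
        skew_undef = (g + c) == 0
        out.append(
            WindowStat(
                contig_id=genome.contig_id,
                start=start0 + 1,
                end=start0 + size,
                gc_content=(g + c) / size,
                gc_skew=0.0 if skew_undef else (g - c) / (g + c),
                mod_count=n_mod,
                skew_undefined=skew_undef,
            )
        )
    return out


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> CorrelationReport:
    """Spearman rho with a percentile-bootstrap confidence interval.

    Pairs are resampled with replacement ``n_boot`` times; CI bounds are
    the alpha/2 and 1-alpha/2 percentiles of the resampled rho values.
    Constant input is flagged and reported as rho 0, not significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant input to spearman_bootstrap; rho reported as 0")
        return CorrelationReport(0.0, 0.0, 0.0, n_boot, alpha, flagged=True)
    rho = _spearman(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    # rank row-wise, then Pearson on ranks == Spearman, vectorised
    rx = stats.rankdata(x[idx], axis=1)
    ry = stats.rankdata(y[idx], axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boot = (rx * ry).sum(axis=1) / denom
    boot = boot[np.isfinite(boot)]
    ci_low = float(np.percentile(boot, 100 * alpha / 2))
    ci_high = float(np.percentile(boot, 100 * (1 - alpha / 2)))
    return CorrelationReport(rho, ci_low, ci_high, n_boot, alpha)


def build_region_sets(
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
    islands: Sequence[tuple[str, int, int]] | None = None,
    upstream_len: int = 120,
) -> dict[str, list[RegionSet]]:
    """Two genome partitions used by the region-bias analysis.

    ``mge_core``: island intervals vs the rest of the genome.
    ``functional``: TSC-upstream stretches (``upstream_len`` bp 5' of each
    start codon on the gene's strand), then coding (CDS not claimed by a
    TSC-upstream region), then noncoding. Upstream regions wrap on
    circular contigs and are truncated on linear ones.
    """
    length = genome.length
    contig = genome.contig_id

    # functional partition via a per-base label array
    # 0 noncoding, 1 coding, 2 tsc_upstream (highest precedence)
    labels = np.zeros(length, dtype=np.int8)
    for g in genes:
        if g.contig_id != contig:
            continue
        labels[g.start - 1 : g.end] = np.maximum(labels[g.start - 1 : g.end], 1)
    for g in genes:
        if g.contig_id != contig:
            continue
        if g.strand == "+":
            lo, hi = g.tsc_position - upstream_len, g.tsc_position - 1
        else:
            lo, hi = g.tsc_position + 1, g.tsc_position + upstream_len
        for pos in range(lo, hi + 1):
            if 1 <= pos <= length:
                labels[pos - 1] = 2
            elif genome.circular:
                labels[(pos - 1) % length] = 2
            # linear overhangs truncated

    mge_mask = np.zeros(length, dtype=bool)
    for c, s, e in islands or []:
        if c == contig:
            mge_mask[max(s, 1) - 1 : min(e, length)] = True

    def runs(mask: np.ndarray) -> list[tuple[str, int, int]]:
        out = []
        padded = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
        starts = np.flatnonzero(padded == 1) + 1
        ends = np.flatnonzero(padded == -1)
        return [(contig, int(s), int(e)) for s, e in zip(starts, ends)]

    functional = [
        RegionSet("tsc_upstream", runs(labels == 2)),
        RegionSet("coding", runs(labels == 1)),
        RegionSet("noncoding", runs(labels == 0)),
    ]
    mge_core = [
        RegionSet("mge", runs(mge_mask)),
        RegionSet("core", runs(~mge_mask)),
    ]
    return {"functional": functional, "mge_core": mge_core}


def region_bias(
    mods: Sequence[ModifiedBase],
    regions: Sequence[RegionSet],
    genome: GenomeSequence,
) -> list[RegionBias]:
    """Observed vs expected modification counts for one genome partition.

    Expected counts are proportional to each class's share of the genome;
    Z = (F_obs - F_exp) / sqrt(F_exp + 1), p = Phi_sf(|Z|). Calls are
    assigned by position alone (strands pooled).
    """
    length = genome.length
    label_of = np.full(length, -1, dtype=np.int32)
    for i, rs in enumerate(regions):
        for c, s, e in rs.intervals:
            if c == genome.contig_id:
                label_of[s - 1 : e] = i
    if np.any(label_of < 0):
        raise ValueError("region sets do not cover the genome")
    positions = [
        m.position for m in mods
        if m.contig_id == genome.contig_id and 1 <= m.position <= length
    ]
    total = len(positions)
    obs = np.zeros(len(regions), dtype=np.int64)
    for pos in positions:
        obs[label_of[pos - 1]] += 1
    out: list[RegionBias] = []
    for i, rs in enumerate(regions):
        f_exp = total * rs.total_length / length
        z = (obs[i] - f_exp) / np.sqrt(f_exp + 1)
        p = float(stats.norm.sf(abs(z)))
        out.append(RegionBias(rs.label, int(obs[i]), float(f_exp), float(z), p))
    return out
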