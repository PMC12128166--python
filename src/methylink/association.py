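"""TSC-relative sliding-window contingency analysis.

For each gene, a window [offset, offset + window) in strand-aware
coordinates relative to the first base of the start codon (negative =
upstream) is inspected in two conditions. Genes whose same-strand
modification count differs between conditions AND whose expression
category shifted contribute to a 2x2 table

    [[a, b], [c, d]]   a: mods up, expression up    b: mods down, up
                       c: mods up, expression down  d: mods down, down

scored by a chi-squared test, raw linkage disequilibrium (first-cell
frequency minus its expectation under independence) and its
margin-normalised value LD' (Lewontin-style). A parameter-grid sweep
with Benjamini-Hochberg control aggregates significant windows into a
per-offset hit profile over the seven central nucleotides of each
significant window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import (
    CategoryShift,
    ContingencyResult,
    GeneModel,
    GenomeSequence,
    ModifiedBase,
    OffsetSummary,
    SweepConfig,
    SweepResult,
)

log = logging.getLogger(__name__)


def ld_prime(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Raw and normalised linkage disequilibrium of a 2x2 table.

    ld_raw = a/n - p_row * p_col with p_row = (a+b)/n, p_col = (a+c)/n.
    ld_norm divides by the largest attainable |ld_raw| given the margins:
    min(p_row*(1-p_col), (1-p_row)*p_col) for positive ld_raw and
    min(p_row*p_col, (1-p_row)*(1-p_col)) for negative. Returns
    (ld_raw, nan) when any margin is zero.
    """
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty contingency table")
    p_row = (a + b) / n
    p_col = (a + c) / n
    ld_raw = a / n - p_row * p_col
    if min(a + b, c + d, a + c, b + d) == 0:
        return ld_raw, math.nan
    if ld_raw > 0:
        ld_max = min(p_row * (1 - p_col), (1 - p_row) * p_col)
    elif ld_raw < 0:
        ld_max = min(p_row * p_col, (1 - p_row) * (1 - p_col))
    else:
        return 0.0, 0.0
    return ld_raw, ld_raw / ld_max


def contingency_p(a: int, b: int, c: int, d: int, correction: bool = True) -> float:
    """Chi-squared p-value (1 df) for a 2x2 table; zero margin -> 1.0."""
    if a + b + c + d < 1:
        raise ValueError("empty contingency table")
    if min(a + b, c + d, a + c, b + d) == 0:
        log.debug("degenerate table (%d,%d,%d,%d): p = 1.0", a, b, c, d)
        return 1.0
    res = stats.chi2_contingency([[a, b], [c, d]], correction=correction)
    return float(res.pvalue)


def _chi2_p_vec(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray, correction: bool
) -> np.ndarray:
    """Vectorised 2x2 chi-squared p; degenerate margins get p = 1."""
    a, b, c, d = (x.astype(float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    ok = (denom > 0) & (n > 0)
    diff = np.abs(a * d - b * c)
    if correction:
        diff = np.maximum(diff - n / 2, 0.0)
    chi2 = np.zeros_like(n)
    np.divide(n * diff**2, denom, out=chi2, where=ok)
    p = np.ones_like(n)
    p[ok] = stats.chi2.sf(chi2[ok], 1)
    return p


def bh_adjust(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, adjusted, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def binomial_direction_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p for k concordant genes out of n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def relative_mod_positions(
    genes: Sequence[GeneModel],
    mods: Sequence[ModifiedBase],
) -> dict[str, np.ndarray]:
    """Sorted TSC-relative coordinates of same-strand calls per gene.

    Relative coordinate r of genomic position p: r = p - tsc on the +
    strand and r = tsc - p on the - strand, so r increases in the gene's
    reading direction and r = 0 is the first base of the start codon.
    """
    by_strand: dict[tuple[str, str], list[int]] = {}
    for m in mods:
        by_strand.setdefault((m.contig_id, m.strand), []).append(m.position)
    arrays = {
        key: np.sort(np.asarray(positions, dtype=np.int64))
        for key, positions in by_strand.items()
    }
    empty = np.empty(0, dtype=np.int64)
    out: dict[str, np.ndarray] = {}
    for g in genes:
        positions = arrays.get((g.contig_id, g.strand), empty)
        if g.strand == "+":
            rel = positions - g.tsc_position
        else:
            rel = np.sort(g.tsc_position - positions)
        out[g.gene_id] = rel
    return out


def _count_in_window(rel: np.ndarray, offsets: np.ndarray, window: int) -> np.ndarray:
    """Calls with relative coordinate in [offset, offset + window), per offset."""
    return np.searchsorted(rel, offsets + window, side="left") - np.searchsorted(
        rel, offsets, side="left"
    )


def window_contingency(
    genes: Sequence[GeneModel],
    mods_a: Sequence[ModifiedBase],
    mods_b: Sequence[ModifiedBase],
    shifts: Mapping[str, CategoryShift],
    offset: int,
    window: int,
    score_cutoff: float = 0.0,
    correction: bool = True,
) -> ContingencyResult:
    """One 2x2 table for one TSC-relative window across all genes.

    A gene is eligible iff its same-strand call counts in the window
    differ between conditions and its category shift is up or down.
    """
    mods_a = [m for m in mods_a if m.nucmod_score >= score_cutoff]
    mods_b = [m for m in mods_b if m.nucmod_score >= score_cutoff]
    rel_a = relative_mod_positions(genes, mods_a)
    rel_b = relative_mod_positions(genes, mods_b)
    a = b = c = d = 0
    off = np.asarray([offset])
    for g in genes:
        shift = shifts.get(g.gene_id)
        if shift is None or shift.direction == "none":
            continue
        count_a = int(_count_in_window(rel_a[g.gene_id], off, window)[0])
        count_b = int(_count_in_window(rel_b[g.gene_id], off, window)[0])
        if count_a == count_b:
            continue
        mod_up = count_b > count_a
        if shift.direction == "up":
            a += mod_up
            b += not mod_up
        else:
            c += mod_up
            d += not mod_up
    if a + b + c + d == 0:
        return ContingencyResult(
            offset, offset + window - 1, 0, 0, 0, 0, 1.0, 0.0, math.nan, window
        )
    p = contingency_p(a, b, c, d, correction=correction)
    ld_raw, ld_norm = ld_prime(a, b, c, d)
    return ContingencyResult(
        offset, offset + window - 1, a, b, c, d, p, ld_raw, ld_norm, window
    )


def central_offsets(offset: int, window: int) -> range:
    """Offsets of the seven central nucleotides of a window at this offset."""
    mid = math.floor(offset + (window - 1) / 2)
    return range(mid - 3, mid + 4)


@dataclass
class SweepLogRow:
    window: int
    k: int
    score_cutoff: float
    offset: int
    a: int
    b: int
    c: int
    d: int
    chi2_p: float
    adjusted_p: float
    ld_raw: float
    ld_norm: float
    significant: bool


@dataclass
class AssociationDataset:
    """Everything one two-condition association run needs."""

    genes: list[GeneModel]
    mods_a: list[ModifiedBase]
    mods_b: list[ModifiedBase]
    counts_a: dict[str, float]
    counts_b: dict[str, float]
    genome: GenomeSequence | None = None

    def filtered(self, base: str | None, cutoff: float) -> tuple[list, list]:
        def keep(mods):
            return [
                m for m in mods
                if m.nucmod_score >= cutoff and (base is None or m.base == base)
            ]

        return keep(self.mods_a), keep(self.mods_b)


def association_sweep(
    dataset: AssociationDataset,
    config: SweepConfig,
    base: str | None = None,
    metric: str = "rpkm",
) -> tuple[SweepResult, list[SweepLogRow]]:
    """Run the full parameter-grid sweep and build the per-offset profile.

    For every grid point (window size x category count x score cutoff)
    window tables are computed at every offset step; BH adjustment is
    applied across the windows of the grid point; whenever a window's
    chi-squared p <= config.significance_p (and the table is
    non-degenerate) the seven central nucleotide offsets get a hit and
    the window's LD' is accumulated into the per-offset mean.

    ``base`` restricts calls to modified adenines ("A") or cytosines
    ("C"); runs for the two bases are kept separate by the caller.
    """
    from .expression import build_profiles, category_shifts

    offsets = np.arange(
        config.offset_range[0], config.offset_range[1] + 1, config.window_step
    )
    if offsets.size == 0:
        raise ValueError("empty offset range")
    genes = [g for g in dataset.genes
             if g.gene_id in dataset.counts_a and g.gene_id in dataset.counts_b]

    shifts_by_k: dict[int, dict[str, CategoryShift]] = {}
    for k in config.category_counts:
        prof_a = build_profiles(dataset.counts_a, genes, k=k, metric=metric)
        prof_b = build_profiles(dataset.counts_b, genes, k=k, metric=metric)
        shifts_by_k[k] = category_shifts(prof_a, prof_b)

    hit_count: dict[int, int] = {}
    ld_sum: dict[int, float] = {}
    ld_signs: dict[int, set] = {}
    rows: list[SweepLogRow] = []
    n_tested = n_sig = n_grid = 0

    for cutoff in config.score_cutoffs:
        mods_a, mods_b = dataset.filtered(base, cutoff)
        rel_a = relative_mod_positions(genes, mods_a)
        rel_b = relative_mod_positions(genes, mods_b)
        for window in config.window_sizes:
            # per-gene call counts for every offset at once
            counts = {}
            for g in genes:
                counts[g.gene_id] = (
                    _count_in_window(rel_a[g.gene_id], offsets, window),
                    _count_in_window(rel_b[g.gene_id], offsets, window),
                )
            for k in config.category_counts:
                n_grid += 1
                shifts = shifts_by_k[k]
                av = np.zeros(offsets.size, dtype=np.int64)
                bv = np.zeros_like(av)
                cv = np.zeros_like(av)
                dv = np.zeros_like(av)
                for g in genes:
                    direction = shifts[g.gene_id].direction
                    if direction == "none":
                        continue
                    ca, cb = counts[g.gene_id]
                    differs = ca != cb
                    mod_up = differs & (cb > ca)
                    mod_down = differs & (cb < ca)
                    if direction == "up":
                        av += mod_up
                        bv += mod_down
                    else:
                        cv += mod_up
                        dv += mod_down
                pvec = _chi2_p_vec(av, bv, cv, dv, config.yates_correction)
                adjusted, _ = bh_adjust(pvec, config.fdr_alpha)
                for i, off in enumerate(offsets):
                    a, b, c, d = int(av[i]), int(bv[i]), int(cv[i]), int(dv[i])
                    n = a + b + c + d
                    degenerate = n == 0 or min(a + b, c + d, a + c, b + d) == 0
                    ld_raw, ld_norm = (
                        ld_prime(a, b, c, d) if n else (0.0, math.nan)
                    )
                    sig = (not degenerate) and pvec[i] <= config.significance_p
                    n_tested += 1
                    rows.append(
                        SweepLogRow(
                            window, k, cutoff, int(off), a, b, c, d,
                            float(pvec[i]), float(adjusted[i]),
                            ld_raw, ld_norm, sig,
                        )
                    )
                    if sig:
                        n_sig += 1
                        for pos in central_offsets(int(off), window):
                            hit_count[pos] = hit_count.get(pos, 0) + 1
                            ld_sum[pos] = ld_sum.get(pos, 0.0) + ld_norm
                            ld_signs.setdefault(pos, set()).add(
                                "positive" if ld_norm > 0 else "negative"
                            )

    summaries = []
    for pos in sorted(hit_count):
        signs = ld_signs[pos]
        profile = signs.pop() if len(signs) == 1 else "mixed"
        summaries.append(
            OffsetSummary(pos, hit_count[pos], ld_sum[pos] / hit_count[pos], profile)
        )
    result = SweepResult(
        offsets=summaries,
        n_grid_points=n_grid,
        n_windows_tested=n_tested,
        n_windows_significant=n_sig,
    )
    log.info(
        "sweep: %d grid points, %d windows tested, %d significant",
        n_grid, n_tested, n_sig,
    )
    return result, rows
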