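"""Expression normalisation (RPKM / TPM) and equal-size category analysis.

RPKM_i = count_i * 1e9 / total_mapped / length_i
R_i    = count_i / length_i
TPM_i  = 1e6 * R_i / sum(R)

Genes are binned into k categories of (near-)equal size by expression
rank; a gene "shifts" when its category differs between two conditions.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .models import CategoryShift, ExpressionProfile, GeneModel

log = logging.getLogger(__name__)


def compute_rpkm(
    counts: Sequence[float],
    gene_lengths: Sequence[int],
    total_mapped: float,
) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    return counts * 1e9 / total_mapped / lengths


def compute_tpm(
    counts: Sequence[float], gene_lengths: Sequence[int]
) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    r = counts / lengths
    total = r.sum()
    if total == 0:
        log.warning("all length-normalised counts are zero; TPM set to 0")
        return np.zeros_like(r)
    return 1e6 * r / total


def categorize(
    values: Mapping[str, float], k: int
) -> dict[str, int]:
    """Assign each gene an expression category 0..k-1 of near-equal size.

    Genes are ranked ascending by value with gene_id as a deterministic
    tie-break; when n is not divisible by k the extra genes go to the
    lowest categories. Higher category means higher expression.
    """
    n = len(values)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    order = sorted(values, key=lambda g: (values[g], g))
    base, extra = divmod(n, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    categories: dict[str, int] = {}
    idx = 0
    for cat, size in enumerate(sizes):
        for gene_id in order[idx : idx + size]:
            categories[gene_id] = cat
        idx += size
    return categories


def build_profiles(
    counts: Mapping[str, float],
    genes: Sequence[GeneModel],
    k: int = 3,
    metric: str = "rpkm",
    total_mapped: float | None = None,
) -> dict[str, ExpressionProfile]:
    """Full per-condition expression table: counts -> RPKM/TPM -> category.

    ``total_mapped`` defaults to the sum of the supplied counts.
    """
    gene_ids = [g.gene_id for g in genes if g.gene_id in counts]
    missing = [g.gene_id for g in genes if g.gene_id not in counts]
    if missing:
        log.warning("%d genes without counts dropped (e.g. %s)", len(missing), missing[0])
    lengths = {g.gene_id: g.length for g in genes}
    count_vec = np.array([counts[g] for g in gene_ids], dtype=float)
    length_vec = np.array([lengths[g] for g in gene_ids], dtype=float)
    total = total_mapped if total_mapped is not None else float(count_vec.sum())
    rpkm = compute_rpkm(count_vec, length_vec, total)
    tpm = compute_tpm(count_vec, length_vec)
    r_vals = count_vec / length_vec
    profiles = {
        g: ExpressionProfile(g, float(c), float(rp), float(rv), float(tp))
        for g, c, rp, rv, tp in zip(gene_ids, count_vec, rpkm, r_vals, tpm)
    }
    metric_values = {
        g: (p.rpkm if metric == "rpkm" else p.tpm) for g, p in profiles.items()
    }
    for gene_id, cat in categorize(metric_values, k).items():
        profiles[gene_id].category = cat
    return profiles


def category_shifts(
    profiles_a: Mapping[str, ExpressionProfile],
    profiles_b: Mapping[str, ExpressionProfile],
) -> dict[str, CategoryShift]:
    """Per-gene category comparison between two conditions (same gene set)."""
    only_a = sorted(set(profiles_a) - set(profiles_b))
    only_b = sorted(set(profiles_b) - set(profiles_a))
    if only_a or only_b:
        raise ValueError(
            f"gene sets differ: {len(only_a)} only in A (e.g. {only_a[:3]}), "
            f"{len(only_b)} only in B (e.g. {only_b[:3]})"
        )
    shifts = {}
    for gene_id, pa in profiles_a.items():
        pb = profiles_b[gene_id]
        if pa.category is None or pb.category is None:
            raise ValueError(f"{gene_id}: categorize before comparing conditions")
        shifts[gene_id] = CategoryShift(gene_id, pa.category, pb.category)
    return shifts
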