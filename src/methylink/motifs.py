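"""IUPAC motif scanning and canonical / non-canonical call classification.

A motif string with lowercase letters ("AgGCcT", "GaTNNNNNGtGG") defines
which positions carry a methyl mark: a lowercase A or C is methylated on
the strand the motif reads on, a lowercase G or T marks the complementary
base on the opposite strand. Sites are located on both strands of a
(possibly circular) genome; palindromic motifs are reported once.
"""

from __future__ import annotations

import logging
import re
from collections import Counter

from .models import GenomeSequence, ModifiedBase, MotifSite, MotifSpec, MotifStatus

log = logging.getLogger(__name__)

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B",
    "N": "N",
}


def parse_motif(spec_string: str, name: str | None = None) -> MotifSpec:
    """Parse a motif string whose lowercase letters mark methylated positions."""
    fwd, rev = [], []
    for i, ch in enumerate(spec_string):
        upper = ch.upper()
        if upper not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC letter {ch!r} in motif {spec_string!r}")
        if ch.islower():
            if upper in ("A", "C"):
                fwd.append(i)
            elif upper in ("G", "T"):
                rev.append(i)
            else:
                raise ValueError(
                    f"methylated position {i} in {spec_string!r} must resolve to a base"
                )
    return MotifSpec(
        name=name or spec_string.upper(),
        iupac=spec_string.upper(),
        fwd_methyl_offsets=tuple(fwd),
        rev_methyl_offsets=tuple(rev),
    )


def iupac_revcomp(iupac: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[ch] for ch in reversed(iupac))


def is_palindromic(iupac: str) -> bool:
    return iupac_revcomp(iupac) == iupac


def _iupac_regex(iupac: str) -> re.Pattern:
    pattern = "".join(
        ch if len(IUPAC_SETS[ch]) == 1 else f"[{IUPAC_SETS[ch]}]" for ch in iupac
    )
    return re.compile(f"(?=({pattern}))")


def _methylatable(
    motif: MotifSpec, contig_id: str, start: int, orientation: str, length: int,
    circular: bool,
) -> tuple[tuple[int, str, str], ...]:
    """Genomic (position, strand, expected_base) for each methylatable offset."""
    end = start + motif.length - 1
    entries = []
    for off in motif.fwd_methyl_offsets:
        base = motif.iupac[off]
        if orientation == "+":
            entries.append((start + off, "+", base))
        else:
            entries.append((end - off, "-", base))
    for off in motif.rev_methyl_offsets:
        base = _IUPAC_COMPLEMENT[motif.iupac[off]]
        if orientation == "+":
            entries.append((start + off, "-", base))
        else:
            entries.append((end - off, "+", base))
    if circular:
        entries = [((p - 1) % length + 1, s, b) for p, s, b in entries]
    return tuple(sorted(entries))


def scan_motif(genome: GenomeSequence, motif: MotifSpec) -> list[MotifSite]:
    """All occurrences of a motif on both strands of a genome.

    Reverse-complement matches are reported with orientation "-";
    palindromic motifs are reported once (orientation "+"). On circular
    genomes the scan wraps across the origin. Overlapping occurrences
    are all reported.
    """
    if motif.length > genome.length:
        raise ValueError("motif longer than genome")
    seq = genome.sequence
    wrap = motif.length - 1 if genome.circular else 0
    scan_seq = seq + seq[:wrap]
    patterns = [("+", _iupac_regex(motif.iupac))]
    if not is_palindromic(motif.iupac):
        patterns.append(("-", _iupac_regex(iupac_revcomp(motif.iupac))))
    sites: list[MotifSite] = []
    seen: set[tuple[int, str]] = set()
    for orientation, regex in patterns:
        for match in regex.finditer(scan_seq):
            start = match.start() + 1
            if start > genome.length:  # duplicate from the wrap copy
                continue
            if (start, orientation) in seen:
                continue
            seen.add((start, orientation))
            sites.append(
                MotifSite(
                    contig_id=genome.contig_id,
                    start=start,
                    end=start + motif.length - 1,
                    orientation=orientation,
                    motif_name=motif.name,
                    methylatable_positions=_methylatable(
                        motif, genome.contig_id, start, orientation,
                        genome.length, genome.circular,
                    ),
                )
            )
    sites.sort(key=lambda s: (s.start, s.orientation))
    return sites


def classify_modifications(
    mods: list[ModifiedBase], sites: list[MotifSite]
) -> tuple[list[ModifiedBase], list[ModifiedBase]]:
    """Split calls into canonical (at a methylatable motif position) and the rest.

    A canonical match requires position, strand AND base identity with the
    motif's methylatable base; a positional match with the wrong base is
    demoted to non-canonical with a warning.
    """
    lookup: dict[tuple[str, int, str], str] = {}
    for site in sites:
        for pos, strand, base in site.methylatable_positions:
            lookup[(site.contig_id, pos, strand)] = base
    canonical, noncanonical = [], []
    n_demoted = 0
    for mod in mods:
        expected = lookup.get((mod.contig_id, mod.position, mod.strand))
        if expected is None:
            noncanonical.append(mod)
        elif expected in ("A", "C") and mod.base not in ("N", expected):
            n_demoted += 1
            noncanonical.append(mod)
        else:
            canonical.append(mod)
    if n_demoted:
        log.warning(
            "%d calls at motif positions demoted to non-canonical (base mismatch)",
            n_demoted,
        )
    log.info(
        "classified %d calls: %d canonical, %d non-canonical",
        len(mods), len(canonical), len(noncanonical),
    )
    return canonical, noncanonical


def motif_status(
    sites: list[MotifSite],
    mods: list[ModifiedBase],
    score_cutoff: float = 21.0,
) -> tuple[list[MotifStatus], Counter]:
    """Per-site methylation status and a fully/partially/unmethylated census.

    A methylatable position counts as methylated when some call at that
    (position, strand) has score >= score_cutoff.
    """
    best_score: dict[tuple[str, int, str], float] = {}
    for mod in mods:
        key = (mod.contig_id, mod.position, mod.strand)
        if mod.nucmod_score > best_score.get(key, -1.0):
            best_score[key] = mod.nucmod_score
    statuses: list[MotifStatus] = []
    summary: Counter = Counter(
        fully_methylated=0, partially_methylated=0, unmethylated=0
    )
    for site in sites:
        scores = tuple(
            best_score.get((site.contig_id, pos, strand), 0.0)
            for pos, strand, _base in site.methylatable_positions
        )
        n_met = sum(1 for s in scores if s >= score_cutoff)
        if n_met == len(scores):
            status = "fully_methylated"
        elif n_met == 0:
            status = "unmethylated"
        else:
            status = "partially_methylated"
        summary[status] += 1
        statuses.append(MotifStatus(site, status, scores))
    return statuses, summary
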