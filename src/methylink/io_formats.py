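"""Readers and writers for the external formats the pipeline consumes.

FASTA genomes, ipdSummary-style base-modification GFF3, CDS annotation
GFF3, BED interval files and tab-separated result tables. Everything is
normalised to 1-based inclusive coordinates on read.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .models import (
    GeneModel,
    GenomeSequence,
    ModifiedBase,
)

log = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")


def read_genome_fasta(path: str | Path, circular: bool = True) -> list[GenomeSequence]:
    """Read a multi-record FASTA into GenomeSequence objects.

    Lowercase letters are uppercased; any character outside {A,C,G,T,N}
    is mapped to N (count logged). Duplicate contig ids and empty files
    are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    genomes: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            log.warning("%s: %d non-ACGTN characters mapped to N", rec.id, n_bad)
            seq = _NON_ACGTN.sub("N", seq)
        genomes.append(GenomeSequence(rec.id, seq, circular=circular))
    return genomes


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, val = chunk.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


_MOD_BASE_FOR_TYPE = {"m6A": "A", "m4C": "C"}


def read_modifications_gff(
    path: str | Path,
    min_score: float = 0.0,
    genome: GenomeSequence | None = None,
) -> list[ModifiedBase]:
    """Read ipdSummary-style kinModCall GFF3 into ModifiedBase records.

    Records scoring below ``min_score`` are dropped. The modified base is
    inferred from the feature type (m6A -> A, m4C -> C); for bare
    ``modified_base`` features it is looked up in ``genome`` when given.
    Malformed records are skipped with a warning; if every record is
    malformed the read fails.
    """
    mods: list[ModifiedBase] = []
    n_lines = n_malformed = n_filtered = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
                fields = fields[:8] + [" ".join(fields[8:])] if len(fields) > 9 else fields
            if len(fields) < 8:
                n_lines += 1
                n_malformed += 1
                log.warning("%s:%d: too few columns, skipped", path, lineno)
                continue
            n_lines += 1
            contig, _source, ftype, start_s, _end_s, score_s, strand, _frame = fields[:8]
            attrs = _parse_gff_attributes(fields[8]) if len(fields) > 8 else {}
            if ftype not in _MOD_BASE_FOR_TYPE and ftype != "modified_base":
                n_malformed += 1
                log.warning("%s:%d: unexpected feature type %r, skipped", path, lineno, ftype)
                continue
            try:
                position = int(start_s)
                score = float(score_s)
            except ValueError:
                n_malformed += 1
                log.warning("%s:%d: malformed coordinate or score, skipped", path, lineno)
                continue
            if strand == ".":
                log.warning("%s:%d: strand '.', treating as '+'", path, lineno)
                strand = "+"
            if strand not in ("+", "-"):
                n_malformed += 1
                log.warning("%s:%d: malformed strand %r, skipped", path, lineno, strand)
                continue
            if score < min_score:
                n_filtered += 1
                continue
            flagged = False
            base = _MOD_BASE_FOR_TYPE.get(ftype)
            if base is None:
                if genome is not None and genome.contig_id == contig:
                    base = genome.base_at(position, strand)
                    if base not in ("A", "C"):
                        flagged = True
                else:
                    base = "N"
                    flagged = True
            coverage = int(float(attrs.get("coverage", 0)))
            ipd = float(attrs["IPDRatio"]) if "IPDRatio" in attrs else None
            mods.append(
                ModifiedBase(
                    contig_id=contig,
                    position=position,
                    strand=strand,
                    base=base,
                    mod_type=ftype,
                    nucmod_score=score,
                    coverage=coverage,
                    ipd_ratio=ipd,
                    flagged=flagged,
                )
            )
    if n_lines and n_malformed == n_lines:
        raise ValueError(f"{path}: all {n_lines} records malformed")
    log.info(
        "%s: kept %d modification calls (%d below score %.4g, %d malformed)",
        path, len(mods), n_filtered, min_score, n_malformed,
    )
    return mods


def read_annotation_gff(path: str | Path) -> list[GeneModel]:
    """Read protein-coding features (CDS, falling back to gene) from GFF3."""
    cds: list[GeneModel] = []
    genes: list[GeneModel] = []
    n_anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                continue
            contig, _src, ftype, start_s, end_s, _score, strand, _frame = fields[:8]
            if ftype not in ("CDS", "gene"):
                continue
            start, end = int(start_s), int(end_s)
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end")
            attrs = _parse_gff_attributes(fields[8]) if len(fields) > 8 else {}
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if gene_id is None:
                n_anon += 1
                gene_id = f"feature_{lineno}"
                log.warning("%s:%d: feature without ID, assigned %s", path, lineno, gene_id)
            model = GeneModel(gene_id, contig, start, end, strand)
            (cds if ftype == "CDS" else genes).append(model)
    result = cds if cds else genes
    log.info("%s: read %d gene models (%d without ID)", path, len(result), n_anon)
    return result


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals, converting 0-based half-open to 1-based inclusive."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            contig, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            intervals.append((contig, start0 + 1, end0))
    return intervals


def _format_value(value: object) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    if value is None:
        return "NA"
    return str(value)


def write_table(records: Sequence, path: str | Path) -> None:
    """Write homogeneous dataclass records as TSV (header + one row each).

    Floats are rendered with 6 significant digits; NaN/None become NA.
    Derived read-only properties are not written.
    """
    path = Path(path)
    if records:
        if len({type(r) for r in records}) != 1:
            raise TypeError("write_table requires records of one type")
        fields = [f.name for f in dataclasses.fields(records[0])]
    else:
        fields = []
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for rec in records:
            fh.write(
                "\t".join(_format_value(getattr(rec, f)) for f in fields) + "\n"
            )


def read_table(path: str | Path, record_type: type) -> list:
    """Read a TSV written by :func:`write_table` back into dataclasses."""
    import typing

    hints = typing.get_type_hints(record_type)
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            return []
        columns = header.split("\t")
        for line in fh:
            values = line.rstrip("\n").split("\t")
            kwargs = {}
            for name, raw in zip(columns, values):
                typ = hints.get(name, str)
                kwargs[name] = _coerce(raw, typ)
            records.append(record_type(**kwargs))
    return records


def _coerce(raw: str, typ) -> object:
    import typing

    origin = typing.get_origin(typ)
    if origin is typing.Union:
        args = [a for a in typing.get_args(typ) if a is not type(None)]
        if raw == "NA":
            return None
        typ = args[0]
    if raw == "NA":
        return math.nan if typ is float else None
    if typ is bool:
        return raw == "True"
    if typ is int:
        return int(raw)
    if typ is float:
        return float(raw)
    if origin is tuple:
        return tuple() if raw == "()" else tuple(raw.strip("()").split(","))
    return raw


def write_genome_fasta(genomes: Iterable[GenomeSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.contig_id}\n")
            for i in range(0, g.length, 70):
                fh.write(g.sequence[i : i + 70] + "\n")


def write_modifications_gff(mods: Sequence[ModifiedBase], path: str | Path) -> None:
    """Write modification calls in the ipdSummary kinModCall dialect."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in mods:
            attrs = f"coverage={m.coverage}"
            if m.ipd_ratio is not None:
                attrs += f";IPDRatio={m.ipd_ratio:.2f}"
            fh.write(
                f"{m.contig_id}\tkinModCall\t{m.mod_type}\t{m.position}\t{m.position}"
                f"\t{m.nucmod_score:.6g}\t{m.strand}\t.\t{attrs}\n"
            )


def write_annotation_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\tmethylink\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0"
                f"\tID={g.gene_id}\n"
            )


def read_counts_tsv(path: str | Path) -> dict[str, float]:
    """Read a two-column gene_id/count table (header optional)."""
    counts: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            gene_id, _, value = line.partition("\t")
            if gene_id.lower() in ("gene_id", "gene", "id"):
                continue
            counts[gene_id] = float(value)
    return counts


def write_counts_tsv(counts: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcount\n")
        for gene_id in sorted(counts):
            fh.write(f"{gene_id}\t{counts[gene_id]:.6g}\n")
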