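"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
* FASTA (nucleotide or amino acid) via Biopython.
* Gene tables: a GFF3-like tab-separated dialect with columns
  ``contig, source, type, start, end, score, strand, frame, attributes``
  where ``score`` is the caller's coding-potential score and ``attributes``
  is a ``key=value;...`` string that may carry ``genetic_code`` and
  ``protein``. Coordinates are 1-based inclusive; strand must be ``+``/``-``.
* Hit tables: 12-column tabular alignment output
  (query, target, pident, length, mismatch, gapopen, qstart, qend,
  sstart, send, evalue, bitscore). Reverse-strand subject intervals
  (sstart > send) are normalised on load.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ContigRecord, GeneCall, SearchHit

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> list[ContigRecord]:
    """Read FASTA into ContigRecords, erroring on duplicate or empty records."""
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for id {rec.id!r}")
        records.append(ContigRecord(id=rec.id, sequence=seq))
    logger.info("read_fasta: %s -> %d records", path, len(records))
    return records


def write_fasta(records: Iterable[ContigRecord], path: PathLike,
                width: int = 80) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def read_gene_table(path: PathLike) -> list[GeneCall]:
    """Read the GFF3-like gene table; genes grouped by contig, sorted by start,
    with 1-based ``gene_index`` assigned per contig."""
    rows: list[tuple] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            contig, _source, _type, start, end, score, strand, _frame, attrs = fields
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}:{lineno}: start > end ({start_i} > {end_i})")
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: invalid strand {strand!r} (must be + or -)"
                )
            attr_map = _parse_attributes(attrs)
            rows.append((contig, start_i, end_i, strand, float(score),
                         int(attr_map.get("genetic_code", 11)),
                         attr_map.get("protein", "")))

    genes: list[GeneCall] = []
    by_contig: dict[str, list[tuple]] = {}
    order: list[str] = []
    for row in rows:
        if row[0] not in by_contig:
            order.append(row[0])
        by_contig.setdefault(row[0], []).append(row)
    for contig in order:
        contig_rows = sorted(by_contig[contig], key=lambda r: (r[1], r[2]))
        for idx, (cid, start, end, strand, score, code, protein) in enumerate(
            contig_rows, start=1
        ):
            genes.append(GeneCall(contig_id=cid, gene_index=idx, start=start,
                                  end=end, strand=strand, protein=protein,
                                  coding_score=score, genetic_code=code))
    logger.info("read_gene_table: %s -> %d genes on %d contigs",
                path, len(genes), len(by_contig))
    return genes


def write_gene_table(genes: Iterable[GeneCall], path: PathLike,
                     source: str = "mgvkit") -> None:
    with open(path, "w") as handle:
        for g in genes:
            attrs = f"genetic_code={g.genetic_code}"
            if g.protein:
                attrs += f";protein={g.protein}"
            handle.write(
                f"{g.contig_id}\t{source}\tCDS\t{g.start}\t{g.end}\t"
                f"{g.coding_score:g}\t{g.strand}\t0\t{attrs}\n"
            )


def _parse_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_hit_table(path: PathLike) -> list[SearchHit]:
    """Read 12-column tabular search hits; subject intervals normalised."""
    hits: list[SearchHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            (query, target, pident, length, mismatch, gapopen,
             qstart, qend, sstart, send, evalue, bitscore) = fields
            hits.append(SearchHit.normalised(
                query_id=query, target_id=target,
                percent_identity=float(pident), alignment_length=int(length),
                mismatches=int(mismatch), gap_opens=int(gapopen),
                qstart=int(qstart), qend=int(qend),
                sstart=int(sstart), send=int(send),
                e_value=float(evalue), bit_score=float(bitscore)))
    logger.info("read_hit_table: %s -> %d hits", path, len(hits))
    return hits


def write_hit_table(hits: Iterable[SearchHit], path: PathLike) -> None:
    with open(path, "w") as handle:
        for h in hits:
            sstart, send = h.sstart, h.send
            if h.subject_reversed:
                sstart, send = send, sstart
            handle.write(
                f"{h.query_id}\t{h.target_id}\t{h.percent_identity:.3f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.qstart}\t{h.qend}\t{sstart}\t{send}\t"
                f"{h.e_value:g}\t{h.bit_score:g}\n"
            )


def group_hits_by_query(hits: Sequence[SearchHit]) -> dict[str, list[SearchHit]]:
    grouped: dict[str, list[SearchHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return grouped
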