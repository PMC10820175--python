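"""Promoter extraction and IO.

Promoters are the 1-kb windows immediately upstream of a gene's
transcription start (positions -1000 ... -1 in the usual convention),
reported 5'->3' relative to the gene: on the minus strand the forward
genomic slice is reverse-complemented.  All internal coordinates are
0-based half-open on the forward genomic strand (BED convention); the
-1...-1000 convention is translated at the boundary.

The TSS is taken from the gene-level feature (5' end of the gene), i.e.
gene start on '+', gene end on '-'.  Windows clipped at a chromosome edge
are kept at their actual shorter length and flagged ``truncated``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_NORMALIZE = str.maketrans("U", "T")
_VALID = set("ACGTN")

_HEADER_RE = re.compile(r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)$")


def normalize_seq(seq: str) -> str:
    """Uppercase, map U->T, and replace residual non-ACGT characters by N."""
    s = seq.upper().translate(_NORMALIZE)
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class PromoterRecord:
    """One gene's promoter sequence with genomic provenance.

    ``window_start``/``window_end`` are 0-based half-open forward-strand
    coordinates; ``seq`` is gene-oriented (reverse-complemented for '-').
    """

    gene_id: str
    seq: str
    source_chrom: str = ""
    window_start: int = 0
    window_end: int = 0
    strand: str = "+"
    truncated: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.window_end - self.window_start != len(self.seq):
            raise ValueError(
                f"{self.gene_id}: window [{self.window_start},{self.window_end}) "
                f"does not match sequence length {len(self.seq)}"
            )


@dataclass
class GeneSet:
    """An ordered focal gene list, e.g. the top-100 up-regulated genes of a contrast."""

    name: str
    gene_ids: list[str] = field(default_factory=list)
    max_genes: int | None = None

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class SkippedGene:
    gene_id: str
    chrom: str
    reason: str


def read_gene_list(path: str | Path, max_genes: int | None = None, name: str | None = None) -> GeneSet:
    """Read a ranked gene list (one ID per line, most significant first).

    Blank lines and '#' comments are ignored; duplicates are dropped keeping
    the first occurrence; the list is truncated to ``max_genes`` if set
    (e.g. 100 for a top-100 set).
    """
    path = Path(path)
    seen: dict[str, None] = {}
    for line in path.read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        seen.setdefault(token.split()[0], None)
    ids = list(seen)
    if not ids:
        raise ValueError(f"empty gene set: {path}")
    if max_genes is not None:
        ids = ids[:max_genes]
    return GeneSet(name=name or path.stem, gene_ids=ids, max_genes=max_genes)


def _iter_bed(path: Path):
    """Yield (gene_id, chrom, start0, end0, strand) from a BED6 file."""
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{ln}: BED6 requires 6 columns, got {len(parts)}")
        chrom, start, end, name_, _score, strand = parts[:6]
        yield name_, chrom, int(start), int(end), strand


def _iter_gff3(path: Path, feature_type: str, attribute_key: str):
    """Yield (gene_id, chrom, start0, end0, strand) for gene features of a GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    for f in db.features_of_type(feature_type):
        attrs = f.attributes
        if attribute_key in attrs:
            gid = attrs[attribute_key][0]
        elif "locus_tag" in attrs:
            gid = attrs["locus_tag"][0]
        else:
            gid = f.id
        yield gid, f.seqid, f.start - 1, f.end, f.strand


def extract_promoters(
    genome: str | Path,
    annotation: str | Path,
    window_len: int = 1000,
    feature_type: str = "gene",
    attribute_key: str = "ID",
    skip_log: str | Path | None = None,
    exclude_overlapping: bool = False,
) -> list[PromoterRecord]:
    """Extract TSS-anchored upstream windows for every gene in an annotation.

    For a '+' gene with 1-based start S the promoter covers 1-based
    [S - window_len, S - 1]; for a '-' gene with 1-based end E it covers
    [E + 1, E + window_len], reverse-complemented.  Windows clipped at a
    chromosome edge come back shorter and flagged ``truncated``.  Genes
    without a usable strand are skipped (logged, and written to ``skip_log``
    as TSV if given); a chromosome absent from the genome is an error.

    With ``exclude_overlapping`` (off by default) a promoter whose window
    intersects another gene's feature interval is skipped too, for studies
    that want upstream regions free of neighboring gene bodies.
    """
    genome = Path(genome)
    annotation = Path(annotation)
    fa = Fasta(str(genome), sequence_always_upper=False, rebuild=True)

    if annotation.suffix.lower() == ".bed":
        features = list(_iter_bed(annotation))
    else:
        features = list(_iter_gff3(annotation, feature_type, attribute_key))

    gene_intervals: dict[str, list[tuple[int, int, str]]] = {}
    if exclude_overlapping:
        for gid, chrom, start0, end0, _ in features:
            gene_intervals.setdefault(chrom, []).append((start0, end0, gid))

    records: list[PromoterRecord] = []
    skipped: list[SkippedGene] = []
    for gid, chrom, start0, end0, strand in features:
        if strand not in ("+", "-"):
            skipped.append(SkippedGene(gid, chrom, "missing-strand"))
            continue
        if chrom not in fa:
            raise ValueError(f"chromosome {chrom!r} (gene {gid}) not present in genome {genome}")
        chrom_len = len(fa[chrom])
        if strand == "+":
            ws, we = max(0, start0 - window_len), start0
        else:
            ws, we = end0, min(chrom_len, end0 + window_len)
        if we <= ws:
            skipped.append(SkippedGene(gid, chrom, "empty-window"))
            continue
        if exclude_overlapping and any(
            og != gid and ws < oe and os_ < we
            for os_, oe, og in gene_intervals.get(chrom, ())
        ):
            skipped.append(SkippedGene(gid, chrom, "overlaps-gene"))
            continue
        raw = fa[chrom][ws:we].seq
        seq = normalize_seq(raw)
        if strand == "-":
            seq = _revcomp(seq)
        records.append(
            PromoterRecord(
                gene_id=gid, seq=seq, source_chrom=chrom,
                window_start=ws, window_end=we, strand=strand,
                truncated=(we - ws) < window_len,
            )
        )

    if skipped:
        logger.warning("skipped %d gene(s) during promoter extraction", len(skipped))
    if skip_log is not None:
        with open(skip_log, "w") as fh:
            fh.write("gene_id\tchrom\treason\n")
            for s in skipped:
                fh.write(f"{s.gene_id}\t{s.chrom}\t{s.reason}\n")
    return records


def write_promoter_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    """Write promoters as FASTA with header ``gene_id chrom:start-end(strand)``."""
    out = []
    for r in records:
        desc = f"{r.source_chrom}:{r.window_start}-{r.window_end}({r.strand})"
        out.append(SeqRecord(Seq(r.seq), id=r.gene_id, description=desc))
    SeqIO.write(out, str(path), "fasta")


def read_promoter_fasta(path: str | Path) -> list[PromoterRecord]:
    """Read a promoter FASTA, recovering provenance from our header format
    when present (otherwise coordinates default to [0, len) on '+')."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_seq(str(rec.seq))
        desc = rec.description.split(None, 1)
        m = _HEADER_RE.match(desc[1]) if len(desc) > 1 else None
        if m:
            records.append(
                PromoterRecord(
                    gene_id=rec.id, seq=seq, source_chrom=m["chrom"],
                    window_start=int(m["start"]), window_end=int(m["end"]),
                    strand=m["strand"],
                )
            )
        else:
            records.append(PromoterRecord(gene_id=rec.id, seq=seq, window_end=len(seq)))
    return records


def subset_by_geneset(
    records: Sequence[PromoterRecord], geneset: GeneSet, missing: str = "error"
) -> list[PromoterRecord]:
    """Select the promoters of a gene set, in gene-set order.

    ``missing`` is 'error' (default) or 'skip' for gene IDs without a promoter.
    """
    by_id = {r.gene_id: r for r in records}
    out = []
    absent = []
    for gid in geneset.gene_ids:
        if gid in by_id:
            out.append(by_id[gid])
        else:
            absent.append(gid)
    if absent and missing == "error":
        raise KeyError(f"{len(absent)} gene(s) of set {geneset.name!r} lack promoters, e.g. {absent[:3]}")
    return out
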