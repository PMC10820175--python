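"""Known cis-element annotation and IUPAC-aware promoter scanning.

A small editable dictionary maps element names (DRE, ARR1AT, MYBST1, ...)
to nucleotide patterns in the IUPAC degenerate alphabet.  Two operations
use it: ``annotate`` attaches element names to a concrete hexamer (same-
length IUPAC match, or a shorter pattern contained at any offset), and
``scan_geneset`` counts overlapping pattern occurrences in each promoter
of a gene set, summarizing how many genes carry the element at least once.

Entries whose sequence is unknown may carry the motif sentinel "-"; they
keep their name in the dictionary but never match anything.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_regex(pattern: str) -> str:
    """Regex equivalent of an IUPAC pattern.  Degenerate codes expand to
    concrete-base classes only, so an N in the subject never matches."""
    parts = []
    for c in pattern:
        if c not in IUPAC_EXPANSION:
            raise ValueError(f"invalid IUPAC character {c!r} in pattern {pattern!r}")
        exp = IUPAC_EXPANSION[c]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return "".join(parts)


def reverse_complement_iupac(pattern: str) -> str:
    """Reverse complement with degenerate codes mapped to their complements."""
    if not set(pattern) <= set(IUPAC_EXPANSION):
        raise ValueError(f"invalid IUPAC pattern {pattern!r}")
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Element:
    name: str
    motif: str  # IUPAC pattern, or "-" for name-only entries
    source: str = ""


@dataclass
class ElementDictionary:
    """Named cis-elements with (possibly degenerate) sequences."""

    entries: list[Element]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("element names must be unique")
        for e in self.entries:
            if e.motif != "-":
                iupac_regex(e.motif)  # validates at load time

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def scannable(self) -> list[Element]:
        return [e for e in self.entries if e.motif != "-"]

    def get(self, name: str) -> Element:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


def load_element_dictionary(path: str | Path | None = None) -> ElementDictionary:
    """Load a dictionary TSV (columns name, iupac, source).  With no path,
    the bundled default (the study's named elements) is loaded."""
    if path is None:
        source = resources.files("promhex").joinpath("data/elements.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    entries = []
    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "name":
            continue
        if len(parts) < 2:
            raise ValueError(f"elements TSV line {ln}: need at least name and iupac columns")
        name, motif = parts[0], parts[1].upper()
        src = parts[2] if len(parts) > 2 else ""
        entries.append(Element(name=name, motif=motif, source=src))
    return ElementDictionary(entries=entries)


def annotate(motif: str, dictionary: ElementDictionary) -> list[str]:
    """Element names matching a concrete hexamer.

    A dictionary pattern matches if it has the same length and its IUPAC
    expansion covers the hexamer, or if it is shorter and matches at any
    offset (e.g. CATTT inside CATTTT).  Longer patterns never match.
    """
    hits = []
    for e in dictionary.scannable:
        if len(e.motif) > len(motif):
            continue
        rx = re.compile(iupac_regex(e.motif))
        if len(e.motif) == len(motif):
            if rx.fullmatch(motif):
                hits.append(e.name)
        elif rx.search(motif):
            hits.append(e.name)
    return hits


@dataclass
class OccurrenceTable:
    """Per-(gene, element) occurrence counts plus per-element summaries.

    ``per_gene``: DataFrame indexed by gene_id, one column per scannable
    element, values are overlapping occurrence counts in that promoter.
    ``summary``: per element, genes_with_hit and fraction_with_hit.
    """

    per_gene: pd.DataFrame
    summary: pd.DataFrame

    def to_tsv(self, per_gene_path: str | Path, summary_path: str | Path) -> None:
        self.per_gene.to_csv(per_gene_path, sep="\t")
        self.summary.to_csv(summary_path, sep="\t", index=False)


def _count_overlapping(rx: re.Pattern, seq: str) -> int:
    return sum(1 for _ in rx.finditer(seq))


def scan_geneset(
    promoters: Sequence,
    elements: ElementDictionary,
    both_strands: bool = False,
) -> OccurrenceTable:
    """Count overlapping element occurrences in each promoter of a gene set.

    With ``both_strands`` the reverse-complement pattern's occurrences are
    added on top (a palindromic pattern is then counted twice per site).
    """
    promoters = list(promoters)
    if not promoters:
        raise ValueError("empty promoter set")
    scannable = elements.scannable
    if not scannable:
        raise ValueError("element dictionary has no scannable entries")

    compiled = {}
    for e in scannable:
        pats = [f"(?={iupac_regex(e.motif)})"]
        if both_strands:
            pats.append(f"(?={iupac_regex(reverse_complement_iupac(e.motif))})")
        compiled[e.name] = [re.compile(p) for p in pats]

    rows = {}
    for p in promoters:
        seq = p if isinstance(p, str) else p.seq
        gid = getattr(p, "gene_id", seq[:12])
        rows[gid] = {
            name: sum(_count_overlapping(rx, seq) for rx in rxs)
            for name, rxs in compiled.items()
        }
    per_gene = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    per_gene.index.name = "gene_id"
    per_gene = per_gene[[e.name for e in scannable]]

    n_genes = len(per_gene)
    genes_with_hit = (per_gene > 0).sum(axis=0)
    summary = pd.DataFrame(
        {
            "element": [e.name for e in scannable],
            "motif": [e.motif for e in scannable],
            "total_occurrences": per_gene.sum(axis=0).to_numpy(),
            "genes_with_hit": genes_with_hit.to_numpy(),
            "fraction_with_hit": genes_with_hit.to_numpy() / n_genes,
        }
    )
    return OccurrenceTable(per_gene=per_gene, summary=summary)


def match_coordinates(
    promoters: Sequence,
    elements: ElementDictionary,
) -> pd.DataFrame:
    """Promoter-local (0-based half-open) coordinates of every element match,
    suitable for BED export."""
    scannable = elements.scannable
    compiled = {e.name: (re.compile(f"(?=({iupac_regex(e.motif)}))"), len(e.motif))
                for e in scannable}
    recs = []
    for p in promoters:
        seq = p if isinstance(p, str) else p.seq
        gid = getattr(p, "gene_id", seq[:12])
        for name, (rx, mlen) in compiled.items():
            for m in rx.finditer(seq):
                recs.append((gid, m.start(), m.start() + mlen, name))
    return pd.DataFrame(recs, columns=["gene_id", "start", "end", "element"])


def write_match_bed(matches: pd.DataFrame, path: str | Path) -> None:
    """Write matches as BED (chrom = gene_id, promoter-local coordinates)."""
    with open(path, "w") as fh:
        for r in matches.itertuples(index=False):
            fh.write(f"{r.gene_id}\t{r.start}\t{r.end}\t{r.element}\n")
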