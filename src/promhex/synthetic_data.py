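"""Seeded synthetic promoter universes with planted motifs.

Stands in for the study's inputs: a background universe of ~1-kb promoters
(emulating the genome-wide Arabidopsis promoter set the null is resampled
from) and focal gene sets (emulating top-100 up-regulated gene lists) whose
promoters carry a motif planted at a known per-promoter copy number.

Background promoters are iid draws from a configurable base composition
(uniform by default); a first-order Markov option exists for robustness
checks.  Planting overwrites bases rather than inserting, so promoter
length — and hence the window denominator — is unchanged.  Every output is
a pure function of the seed.

The generator also writes the universe as a synthetic multi-contig genome
(one gene per contig, alternating strands, with each promoter embedded
immediately upstream of a dummy gene body) plus a BED6 annotation, so that
promoter extraction can be round-tripped against the generator's own
ground-truth records, including minus-strand and edge-truncated cases.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .promoter_io import GeneSet, PromoterRecord, write_promoter_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GENE_BODY_LEN = 120


@dataclass
class Planting:
    """One focal-set construction: plant ``per_promoter_copies`` copies of
    ``motif`` into each of ``n_genes`` fresh background-like promoters."""

    motif: str
    geneset_name: str
    per_promoter_copies: int = 1
    n_genes: int = 100

    def __post_init__(self) -> None:
        if self.per_promoter_copies < 0:
            raise ValueError("per_promoter_copies must be >= 0")
        if not set(self.motif) <= set("ACGT"):
            raise ValueError(f"planted motif must be concrete ACGT, got {self.motif!r}")


@dataclass
class SyntheticConfig:
    n_background: int = 5000
    promoter_len: int = 1000
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    plantings: list[Planting] = field(default_factory=list)
    seed: int = 0
    n_frac: float = 0.0
    n_truncated: int = 0  # background promoters clipped short at a contig edge
    markov: np.ndarray | None = None  # optional 4x4 first-order transition matrix

    def __post_init__(self) -> None:
        probs = np.asarray(self.base_probs, dtype=float)
        if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-12 or (probs < 0).any():
            raise ValueError("base_probs must be 4 non-negative reals summing to 1")
        for p in self.plantings:
            if len(p.motif) > self.promoter_len:
                raise ValueError("planted motif longer than promoter")
        if not 0 <= self.n_frac < 1:
            raise ValueError("n_frac must be in [0, 1)")


def _draw_bases(rng: np.random.Generator, n: int, probs, markov=None) -> np.ndarray:
    if markov is None:
        codes = rng.choice(4, size=n, p=np.asarray(probs, dtype=float))
    else:
        tm = np.asarray(markov, dtype=float)
        codes = np.empty(n, dtype=np.int64)
        codes[0] = rng.choice(4, p=np.asarray(probs, dtype=float))
        for i in range(1, n):
            codes[i] = rng.choice(4, p=tm[codes[i - 1]])
    return codes


def _codes_to_seq(codes: np.ndarray, rng: np.random.Generator, n_frac: float) -> str:
    out = _BASES[codes].copy()
    if n_frac > 0:
        mask = rng.random(out.size) < n_frac
        out[mask] = ord("N")
    return out.tobytes().decode("ascii")


def _random_seq(rng: np.random.Generator, n: int, probs, n_frac=0.0, markov=None) -> str:
    return _codes_to_seq(_draw_bases(rng, n, probs, markov), rng, n_frac)


@dataclass
class SyntheticUniverse:
    """A generated background universe plus everything needed to write the
    matching synthetic genome and annotation."""

    config: SyntheticConfig
    records: list[PromoterRecord]
    gene_bodies: dict[str, str]

    def write_promoter_fasta(self, path: str | Path) -> None:
        write_promoter_fasta(self.records, path)

    def write_genome_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq

        with open(path, "w") as fh:
            for r in self.records:
                body = self.gene_bodies[r.gene_id]
                if r.strand == "+":
                    contig = r.seq + body
                else:
                    contig = body + str(Seq(r.seq).reverse_complement())
                fh.write(f">{r.source_chrom}\n")
                for i in range(0, len(contig), 60):
                    fh.write(contig[i:i + 60] + "\n")

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                body_len = len(self.gene_bodies[r.gene_id])
                if r.strand == "+":
                    gs, ge = r.window_end, r.window_end + body_len
                else:
                    gs, ge = r.window_start - body_len, r.window_start
                fh.write(f"{r.source_chrom}\t{gs}\t{ge}\t{r.gene_id}\t0\t{r.strand}\n")


def generate_background(config: SyntheticConfig) -> SyntheticUniverse:
    """Generate the background promoter universe, one gene per contig.

    Strands alternate (+, -, +, ...).  The first ``n_truncated`` promoters
    are clipped to a random shorter length flush against the contig edge,
    exactly as a real chromosome-edge gene would be, and flagged truncated.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    records, bodies = [], {}
    for i in range(config.n_background):
        gid = f"bg{i + 1:05d}"
        chrom = f"chr{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        if i < config.n_truncated:
            plen = int(rng.integers(50, config.promoter_len))
        else:
            plen = config.promoter_len
        seq = _random_seq(rng, plen, config.base_probs, config.n_frac, config.markov)
        body = _random_seq(rng, _GENE_BODY_LEN, config.base_probs)
        # contig layout: '+' -> [promoter][body]; '-' -> [body][revcomp(promoter)]
        if strand == "+":
            ws, we = 0, plen
        else:
            ws, we = _GENE_BODY_LEN, _GENE_BODY_LEN + plen
        records.append(
            PromoterRecord(
                gene_id=gid, seq=seq, source_chrom=chrom,
                window_start=ws, window_end=we, strand=strand,
                truncated=plen < config.promoter_len,
            )
        )
        bodies[gid] = body
    return SyntheticUniverse(config=config, records=records, gene_bodies=bodies)


@dataclass
class GenesetBundle:
    """A focal gene set with its promoters and the ground-truth planted
    positions (promoter-local, 0-based half-open)."""

    geneset: GeneSet
    records: list[PromoterRecord]
    planting: Planting
    positions: dict[str, list[tuple[int, int]]]

    def write_gene_list(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.geneset.gene_ids) + "\n")

    def write_ground_truth_json(self, path: str | Path, seed: int) -> None:
        payload = {
            "seed": seed,
            "geneset": self.geneset.name,
            "motif": self.planting.motif,
            "per_promoter_copies": self.planting.per_promoter_copies,
            "positions": {g: [list(p) for p in pos] for g, pos in self.positions.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _plant(rng: np.random.Generator, seq: str, motif: str, copies: int,
           max_tries: int = 1000) -> tuple[str, list[tuple[int, int]]]:
    """Overwrite ``copies`` non-overlapping windows of seq with motif."""
    m = len(motif)
    if copies == 0:
        return seq, []
    if copies * m > len(seq):
        raise ValueError(f"cannot place {copies} non-overlapping copies of a {m}-mer "
                         f"in a {len(seq)}-bp promoter")
    chosen: list[tuple[int, int]] = []
    tries = 0
    while len(chosen) < copies:
        if tries >= max_tries:
            raise ValueError("could not place planted copies without overlap")
        tries += 1
        s = int(rng.integers(0, len(seq) - m + 1))
        if all(s + m <= a or s >= b for a, b in chosen):
            chosen.append((s, s + m))
    chosen.sort()
    buf = bytearray(seq, "ascii")
    for s, e in chosen:
        buf[s:e] = motif.encode("ascii")
    return buf.decode("ascii"), chosen


def generate_geneset(config: SyntheticConfig, planting: Planting) -> GenesetBundle:
    """Draw ``n_genes`` fresh background-like promoters and plant the motif.

    The RNG stream is derived from (config.seed, geneset name), so different
    gene sets of the same universe are independent and each is reproducible
    in isolation.
    """
    tag = zlib.crc32(planting.geneset_name.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([config.seed, 1, tag])
    records, positions = [], {}
    for i in range(planting.n_genes):
        gid = f"{planting.geneset_name}_g{i + 1:04d}"
        seq = _random_seq(rng, config.promoter_len, config.base_probs,
                          config.n_frac, config.markov)
        seq, pos = _plant(rng, seq, planting.motif, planting.per_promoter_copies)
        records.append(
            PromoterRecord(
                gene_id=gid, seq=seq, source_chrom=gid,
                window_start=0, window_end=len(seq), strand="+",
            )
        )
        positions[gid] = pos
    geneset = GeneSet(name=planting.geneset_name, gene_ids=[r.gene_id for r in records])
    return GenesetBundle(geneset=geneset, records=records, planting=planting,
                         positions=positions)
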