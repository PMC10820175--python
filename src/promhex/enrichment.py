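"""Resampling-standardized null model and per-hexamer Z-scores.

The null ("standardized promoters") is built by repeatedly drawing random
subsets of the background promoter universe: each replicate samples
``sample_size`` promoters (default 100) uniformly without replacement and
totals every hexamer's count in the subset.  Over ``n_replicates`` (default
1000) independent replicates this yields, per hexamer, the mean and sample
standard deviation of its frequency per 100 promoters.

A focal gene set's observed counts are standardized to the same per-100-
promoter scale and converted to Z-scores:

    z[m] = (observed_freq[m] - null_mean[m]) / null_sd[m]

Hexamers whose null sd is zero get an undefined z (NaN) and are excluded
from ranking.  Ranks are assigned by descending z, ties broken
lexicographically by motif.  No multiple-testing correction is applied —
the output is a Z-score ranking; an approximate two-sided normal p-value
column is included for convenience only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .hexamer_core import HexamerCountVector, count_matrix, enumerate_hexamers


@dataclass
class NullModel:
    """Per-hexamer mean and sd of frequency-per-sample across resampled
    background subsets, together with the sampling parameters and seed.

    Regenerating with identical seed, background, ``sample_size`` and
    ``n_replicates`` reproduces ``mean`` and ``sd`` bit-identically:
    replicate r's draw is a pure function of (seed, r).
    """

    sample_size: int
    n_replicates: int
    seed: int
    mean: np.ndarray
    sd: np.ndarray
    background_size: int
    k: int = 6

    @property
    def degenerate(self) -> bool:
        """True when the null carries no variance at all (e.g. the background
        is exactly one sample's worth of promoters)."""
        return bool(np.all(self.sd == 0))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sample_size": self.sample_size,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "background_size": self.background_size,
            "k": self.k,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NullModel":
        d = json.loads(Path(path).read_text())
        return cls(
            sample_size=d["sample_size"], n_replicates=d["n_replicates"],
            seed=d["seed"], background_size=d["background_size"], k=d["k"],
            mean=np.asarray(d["mean"], dtype=float), sd=np.asarray(d["sd"], dtype=float),
        )


def build_null(
    background: Sequence | np.ndarray,
    sample_size: int = 100,
    n_replicates: int = 1000,
    seed: int = 0,
    k: int = 6,
) -> NullModel:
    """Build the resampled background null.

    ``background`` is a sequence of promoters (records or plain sequences) or
    a precomputed per-promoter count matrix from
    :func:`promhex.hexamer_core.count_matrix`.  Each replicate draws
    ``sample_size`` distinct promoters; replicates are independent, so a
    promoter may recur across replicates.  ``sd`` uses the n-1 denominator
    across replicate totals.
    """
    if sample_size < 1 or n_replicates < 1:
        raise ValueError("sample_size and n_replicates must be >= 1")
    if isinstance(background, np.ndarray) and background.ndim == 2:
        mat = background
    else:
        mat, _ = count_matrix(background, k=k)
    n_bg = mat.shape[0]
    if n_bg < sample_size:
        raise ValueError(f"background ({n_bg} promoters) smaller than sample_size ({sample_size})")

    totals = np.empty((n_replicates, 4**k), dtype=np.float64)
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        idx = rng.choice(n_bg, size=sample_size, replace=False)
        totals[r] = mat[idx].sum(axis=0)
    mean = totals.mean(axis=0)
    sd = totals.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(4**k)
    return NullModel(
        sample_size=sample_size, n_replicates=n_replicates, seed=seed,
        mean=mean, sd=sd, background_size=n_bg, k=k,
    )


@dataclass
class EnrichmentTable:
    """Per-hexamer observed standardized frequency, Z-score, rank and
    element annotation for one focal gene set.

    ``df`` is indexed by motif (lexicographic) with columns observed_freq,
    null_mean, null_sd, z, rank (nullable Int64; NA where z undefined),
    elements (comma-joined names) and approx_p.
    """

    name: str
    df: pd.DataFrame
    sample_size: int
    n_promoters: int

    def top_k(self, k: int = 10) -> pd.DataFrame:
        """The k top-ranked motifs (descending z, lexicographic tie-break)."""
        if k < 1:
            raise ValueError("k must be >= 1")
        ranked = self.df[self.df["rank"].notna()].sort_values("rank")
        return ranked.head(k)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.insert(0, "motif", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None,
                 sample_size: int = 100, n_promoters: int = 0) -> "EnrichmentTable":
        df = pd.read_csv(path, sep="\t", dtype={"elements": "string"})
        df = df.set_index("motif")
        df["rank"] = df["rank"].astype("Int64")
        df["elements"] = df["elements"].fillna("")
        return cls(name=name or Path(path).stem, df=df,
                   sample_size=sample_size, n_promoters=n_promoters)


def zscore(
    observed: HexamerCountVector,
    null: NullModel,
    elements=None,
    name: str = "",
) -> EnrichmentTable:
    """Standardize observed counts per ``sample_size`` promoters and score
    against the null.

    The focal set need not contain exactly ``sample_size`` genes: counts are
    divided by the actual set size and rescaled, i.e.
    ``observed_freq = counts * sample_size / n_promoters``.
    """
    if observed.k != null.k or observed.counts.shape != null.mean.shape:
        raise ValueError("observed count vector does not match the null's hexamer universe")
    if observed.n_promoters < 1:
        raise ValueError("observed set must contain at least one promoter")

    idx = enumerate_hexamers(null.k)
    obs_freq = observed.counts * (null.sample_size / observed.n_promoters)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null.sd > 0, (obs_freq - null.mean) / null.sd, np.nan)

    df = pd.DataFrame(
        {
            "observed_freq": obs_freq,
            "null_mean": null.mean,
            "null_sd": null.sd,
            "z": z,
        },
        index=pd.Index(idx.motifs, name="motif"),
    )
    defined = df["z"].notna()
    # descending z; the motif index is lexicographic, so a stable sort on -z
    # breaks ties lexicographically
    order = df.loc[defined, "z"].mul(-1).sort_values(kind="stable").index
    rank = pd.Series(pd.NA, index=df.index, dtype="Int64")
    rank.loc[order] = np.arange(1, len(order) + 1)
    df["rank"] = rank

    if elements is not None:
        from .element_scan import annotate

        df["elements"] = [",".join(annotate(m, elements)) for m in df.index]
    else:
        df["elements"] = ""
    df["approx_p"] = 2 * norm.sf(np.abs(df["z"]))
    return EnrichmentTable(name=name, df=df, sample_size=null.sample_size,
                           n_promoters=observed.n_promoters)


def top_k(table: EnrichmentTable, k: int = 10) -> list[tuple[str, str]]:
    """First k motifs by rank as (motif, comma-joined element names) pairs."""
    head = table.top_k(k)
    return list(zip(head.index, head["elements"]))
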