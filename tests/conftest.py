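"""Shared fixtures: an independent brute-force counting oracle, a small
synthetic universe for unit tests, and the full-scale 10-seed panel used
by the calibration and recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

import promhex as ph

BASES = "ACGT"


def naive_hexamer_counts(seq: str, k: int = 6) -> tuple[dict[str, int], int]:
    """Independent window-by-window oracle: test each length-k substring,
    skip any containing a non-ACGT character.  Returns (counts, n_valid)."""
    counts: dict[str, int] = {}
    n_valid = 0
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if set(w) <= set(BASES):
            counts[w] = counts.get(w, 0) + 1
            n_valid += 1
    return counts, n_valid


def random_seq(rng: np.random.Generator, n: int, n_prob: float = 0.0) -> str:
    alphabet = BASES + ("N" if n_prob > 0 else "")
    probs = [(1 - n_prob) / 4] * 4 + ([n_prob] if n_prob > 0 else [])
    return "".join(rng.choice(list(alphabet), size=n, p=probs))


@pytest.fixture(scope="session")
def dictionary():
    return ph.load_element_dictionary()


@pytest.fixture(scope="session")
def small_universe():
    """300 background promoters, uniform composition, a few truncated."""
    cfg = ph.SyntheticConfig(n_background=300, seed=42, n_truncated=5)
    return ph.generate_background(cfg)


@pytest.fixture(scope="session")
def small_null(small_universe):
    mat, _ = ph.count_matrix(small_universe.records)
    return ph.build_null(mat, sample_size=100, n_replicates=300, seed=42)


@pytest.fixture(scope="session")
def seed_panel():
    """Study-scale panel: for each of 10 seeds, a 5000-promoter uniform
    background, its 1000-replicate null (n = 100 per draw), one
    background-only focal set and one with a single planted CGTCCA copy
    per promoter (100 genes each)."""
    panel = []
    for seed in range(10):
        cfg = ph.SyntheticConfig(n_background=5000, promoter_len=1000, seed=seed)
        uni = ph.generate_background(cfg)
        mat, _ = ph.count_matrix(uni.records)
        null = ph.build_null(mat, sample_size=100, n_replicates=1000, seed=seed)
        unplanted = ph.generate_geneset(
            cfg, ph.Planting(motif="CGTCCA", geneset_name="nullset",
                             per_promoter_copies=0, n_genes=100))
        planted = ph.generate_geneset(
            cfg, ph.Planting(motif="CGTCCA", geneset_name="planted",
                             per_promoter_copies=1, n_genes=100))
        t_null = ph.zscore(ph.aggregate_counts(unplanted.records), null, name="nullset")
        t_planted = ph.zscore(ph.aggregate_counts(planted.records), null, name="planted")
        panel.append({
            "seed": seed,
            "null": null,
            "table_null": t_null,
            "table_planted": t_planted,
        })
    return panel
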