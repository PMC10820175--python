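"""Shared paths and study conditions for the numbered analysis scripts.

The simulated study mirrors the real design: a background universe of 5000
uniform-composition 1-kb promoters standing in for the genome-wide promoter
set, and three focal top-100 gene sets — 'osmotic' (CGTCCA/New3 planted once
per promoter), 'salt' (CCTACC/DRE-like planted once per promoter) and
'control' (nothing planted).  Enrichment uses the study's resampling
parameters: samples of 100 promoters, 1000 replicates.
"""

from pathlib import Path

import promhex as ph

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "sim"       # sequence-scale artifacts (not tracked)
RES = ROOT / "results"               # small tables

SEED = 17
CONFIG = ph.SyntheticConfig(n_background=5000, promoter_len=1000,
                            seed=SEED, n_truncated=25)
SAMPLE_SIZE = 100
N_REPLICATES = 1000

PLANTINGS = {
    "osmotic": ph.Planting(motif="CGTCCA", geneset_name="osmotic",
                           per_promoter_copies=1, n_genes=100),
    "salt": ph.Planting(motif="CCTACC", geneset_name="salt",
                        per_promoter_copies=1, n_genes=100),
    "control": ph.Planting(motif="CGTCCA", geneset_name="control",
                           per_promoter_copies=0, n_genes=100),
}


def ensure_dirs() -> None:
    SIM.mkdir(parents=True, exist_ok=True)
    RES.mkdir(parents=True, exist_ok=True)
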