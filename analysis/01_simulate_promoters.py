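"""Simulate the promoter universe and focal gene sets.

Writes the background as a synthetic multi-contig genome + BED annotation
(so the extraction step can be exercised for real), the ground-truth
promoter FASTA, and per-contrast gene lists, planted-promoter FASTAs and
ground-truth planting positions.
"""

import json

import promhex as ph
from common import CONFIG, PLANTINGS, RES, SIM, ensure_dirs


def main() -> None:
    ensure_dirs()
    uni = ph.generate_background(CONFIG)
    uni.write_genome_fasta(SIM / "genome.fa")
    uni.write_bed(SIM / "genes.bed")
    uni.write_promoter_fasta(SIM / "background_promoters.fa")
    n_trunc = sum(r.truncated for r in uni.records)
    print(f"background universe: {len(uni.records)} promoters of "
          f"{CONFIG.promoter_len} bp ({n_trunc} edge-truncated), seed {CONFIG.seed}")

    manifest = {"seed": CONFIG.seed, "n_background": CONFIG.n_background,
                "genesets": {}}
    for name, planting in PLANTINGS.items():
        bundle = ph.generate_geneset(CONFIG, planting)
        bundle.write_gene_list(SIM / f"{name}_genes.txt")
        ph.write_promoter_fasta(bundle.records, SIM / f"{name}_promoters.fa")
        bundle.write_ground_truth_json(SIM / f"{name}_truth.json", seed=CONFIG.seed)
        n_sites = sum(len(v) for v in bundle.positions.values())
        manifest["genesets"][name] = {
            "motif": planting.motif,
            "per_promoter_copies": planting.per_promoter_copies,
            "n_genes": planting.n_genes,
            "planted_sites": n_sites,
        }
        print(f"geneset {name!r}: {planting.n_genes} genes, planted "
              f"{planting.motif} x{planting.per_promoter_copies}/promoter "
              f"({n_sites} sites)")
    (RES / "simulation_manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"wrote sequences to {SIM}, manifest to {RES / 'simulation_manifest.json'}")


if __name__ == "__main__":
    main()
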