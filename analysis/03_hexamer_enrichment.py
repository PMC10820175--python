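"""Per-contrast hexamer enrichment against the resampled background null.

Builds the standardized-promoter null (samples of 100 background promoters,
1000 replicates) once, then scores each focal gene set's 4096 hexamer
frequencies against it and reports the top-10 motifs with known-element
annotations.
"""

import promhex as ph
from common import N_REPLICATES, RES, SAMPLE_SIZE, SEED, SIM, ensure_dirs


def main() -> None:
    ensure_dirs()
    background = ph.read_promoter_fasta(SIM / "extracted_promoters.fa")
    null = ph.build_null(background, sample_size=SAMPLE_SIZE,
                         n_replicates=N_REPLICATES, seed=SEED)
    null.to_json(RES / "null_model.json")
    print(f"null: {null.n_replicates} samples of {null.sample_size} from "
          f"{null.background_size} background promoters "
          f"(grand mean {null.mean.mean():.2f} per hexamer)")

    dictionary = ph.load_element_dictionary()
    for name in ("osmotic", "salt", "control"):
        geneset = ph.read_gene_list(SIM / f"{name}_genes.txt", max_genes=100)
        promoters = ph.subset_by_geneset(
            ph.read_promoter_fasta(SIM / f"{name}_promoters.fa"), geneset)
        table = ph.zscore(ph.aggregate_counts(promoters), null,
                          elements=dictionary, name=name)
        table.to_tsv(RES / f"enrichment_{name}.tsv")
        print(f"\ntop 10 hexamers, {name} ({len(promoters)} promoters):")
        head = table.top_k(10)[["observed_freq", "z", "elements"]]
        print(head.to_string(float_format=lambda v: f"{v:.2f}"))


if __name__ == "__main__":
    main()
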