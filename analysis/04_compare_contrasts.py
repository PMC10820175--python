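"""Compare enrichment between condition contrasts.

Overlays the Z-score rankings of the three contrasts pairwise (osmotic vs
control, salt vs control, osmotic vs salt), reporting shared and
condition-specific top-10 motifs, and writes scatter data plus labeled
scatter plots in both axis conventions (frequency-vs-Z per contrast, and
Z-vs-Z across contrasts).
"""

import promhex as ph
from common import RES, ensure_dirs

PAIRS = [("control", "osmotic"), ("control", "salt"), ("salt", "osmotic")]


def main() -> None:
    ensure_dirs()
    tables = {
        name: ph.EnrichmentTable.from_tsv(RES / f"enrichment_{name}.tsv", name=name)
        for name in ("osmotic", "salt", "control")
    }
    for x, y in PAIRS:
        comp = ph.compare(tables[x], tables[y])
        stem = f"{y}_vs_{x}"
        comp.to_tsv(RES / f"comparison_{stem}.tsv")
        ph.scatter_data(comp, x_axis="z").to_csv(
            RES / f"scatter_{stem}.tsv", sep="\t", index=False,
            float_format="%.6g")
        ph.plot_scatter(comp, RES / f"scatter_{stem}.svg", x_axis="z")
        print(f"\n{y} vs {x}:")
        print(f"  shared top-10:      {', '.join(comp.shared_top) or '-'}")
        print(f"  specific to {x}: {', '.join(comp.specific_top_x) or '-'}")
        print(f"  specific to {y}: {', '.join(comp.specific_top_y) or '-'}")


if __name__ == "__main__":
    main()
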