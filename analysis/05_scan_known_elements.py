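"""Scan focal-set promoters for known cis-element occurrences.

Uses the bundled element dictionary to count occurrences of each named
element in every promoter of each focal gene set, reporting per-element
totals and the fraction of genes carrying the element at least once, and
writes promoter-local match coordinates as BED.
"""

import pandas as pd

import promhex as ph
from promhex.element_scan import match_coordinates, write_match_bed
from common import RES, SIM, ensure_dirs


def main() -> None:
    ensure_dirs()
    dictionary = ph.load_element_dictionary()
    summaries = []
    for name in ("osmotic", "salt", "control"):
        promoters = ph.read_promoter_fasta(SIM / f"{name}_promoters.fa")
        table = ph.scan_geneset(promoters, dictionary)
        table.per_gene.to_csv(RES / f"occurrences_{name}.tsv", sep="\t")
        write_match_bed(match_coordinates(promoters, dictionary),
                        RES / f"matches_{name}.bed")
        s = table.summary.copy()
        s.insert(0, "geneset", name)
        summaries.append(s)
        frequent = s[s["fraction_with_hit"] >= 0.5]
        print(f"{name}: elements present in >=50% of promoters: "
              f"{', '.join(frequent['element']) or '-'}")
    pd.concat(summaries, ignore_index=True).to_csv(
        RES / "element_scan_summary.tsv", sep="\t", index=False,
        float_format="%.4f")
    print(f"wrote per-gene tables, BEDs and summary to {RES}")


if __name__ == "__main__":
    main()
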