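"""Annotate the primary peak track against the gene models: nearest-gene
assignment by summit-to-TSS distance, metagene region distribution,
200-bp distance histogram, and the genes x 52-bin occupancy matrix.

Reads results/sim/, writes assignments.tsv, region_distribution.csv,
distance_histogram.csv and occupancy_matrix.tsv under results/annotate/.
"""

import argparse
from pathlib import Path

import pandas as pd

from tboxscan.annotate import (
    assign_nearest_gene, distance_histogram, gene_occupancies,
    region_distribution,
)
from tboxscan.core import read_exon_table, read_gene_table, read_peaks


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/annotate"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genes = read_gene_table(args.simdir / "genes.tsv")
    genes = read_exon_table(args.simdir / "exons.tsv", genes)
    peaks = read_peaks(args.simdir / "tf_primary.bed")
    assignments, unassigned = assign_nearest_gene(peaks, genes)

    pd.DataFrame([
        {"scaffold": a.peak.scaffold, "summit": a.peak.summit,
         "score": a.peak.score, "gene_id": a.gene_id,
         "signed_distance": a.signed_distance,
         "region_class": a.region_class, "subclass": a.subclass or ""}
        for a in assignments
    ]).to_csv(args.outdir / "assignments.tsv", sep="\t", index=False)

    counts = region_distribution(assignments)
    pd.Series(counts, name="n_peaks").rename_axis("region").to_csv(
        args.outdir / "region_distribution.csv")

    edges, hist, out_of_range = distance_histogram(assignments)
    pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                  "count": hist}).to_csv(
        args.outdir / "distance_histogram.csv", index=False)

    occ = gene_occupancies(genes, assignments)
    matrix = pd.DataFrame(
        {g: o.bins for g, o in occ.items()}).T
    matrix.columns = [f"bin_{i}" for i in range(52)]
    matrix.rename_axis("gene_id").to_csv(args.outdir / "occupancy_matrix.tsv",
                                         sep="\t")

    proximal = counts["proximal_up"] + counts["proximal_down"]
    central = hist[(edges[:-1] >= -400) & (edges[:-1] < 400)].sum()
    print(f"assigned {len(assignments)} peaks ({len(unassigned)} on "
          f"geneless scaffolds)")
    print(f"region distribution: {proximal} proximal, "
          f"{counts['gene_body']} in gene bodies "
          f"({counts['intron']} intronic after exon subtraction)")
    print(f"{central} of {hist.sum() + out_of_range} summits lie within "
          f"400 bp of a TSS; {out_of_range} beyond +/-20 kb")
    bound = sum(o.total > 0 for o in occ.values())
    strong = sum(o.total >= 25 for o in occ.values())
    print(f"{bound}/{len(genes)} genes bound; {strong} pass the "
          f"sum[-log10 p] >= 25 target-gene cut")
    print(f"wrote {args.outdir}/")


if __name__ == "__main__":
    main()
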