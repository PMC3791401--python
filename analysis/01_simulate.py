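"""Build the synthetic study: a small genome with gene models, a primary TF
peak track with promoter-proximal planted binding, a cofactor track sharing
80% of its sites, planted T-box motif instances, a replicate knockdown
expression table linked to proximal binding, and noisy SPR binding curves
for three motif variants.

Writes the gene table, FASTA, one BED per TF, expression CSV, SPR CSV and a
truth JSON under results/sim/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tboxscan.annotate import assign_nearest_gene, gene_occupancies
from tboxscan.core import write_bed, write_exon_table, write_gene_table
from tboxscan.simulate import (
    SimConfig, plant_motifs, simulate_binding_curve, simulate_cofactor_track,
    simulate_expression, simulate_genome, simulate_peaks,
)

CONSENSUS_V1 = "TTTCACACC"  # strongest-affinity T-box motif core
#: (label, Kd molar, Rmax) for the three measured motif variants
SPR_VARIANTS = [("v1", 14e-9, 1.0), ("v2", 1.1e-6, 1.0), ("v4", 2.9e-6, 1.0)]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    outdir = args.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=args.seed, n_scaffolds=4, n_genes=400,
                    target_fraction=0.5, n_background_peaks=120)
    genes, sequences = simulate_genome(cfg)
    peaks, peak_truth = simulate_peaks(genes, cfg, label="tf_primary")
    cofactor, cof_truth = simulate_cofactor_track(peaks, cfg,
                                                  label="tf_cofactor")
    sequences, motif_truth = plant_motifs(sequences, peaks, CONSENSUS_V1, cfg)

    assignments, _ = assign_nearest_gene(peaks, genes)
    occ = gene_occupancies(genes, assignments)
    proximal = {g: o.window_sums["proximal_lt1kb_up"]
                + o.window_sums["proximal_lt1kb_down"]
                for g, o in occ.items()}
    expression = simulate_expression(genes, proximal, cfg)

    write_gene_table(genes, outdir / "genes.tsv")
    write_exon_table(genes, outdir / "exons.tsv")
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in
         sorted(sequences.items())],
        outdir / "genome.fa", "fasta")
    write_bed(peaks, outdir / "tf_primary.bed")
    write_bed(cofactor, outdir / "tf_cofactor.bed")
    expression.to_csv(outdir / "expression.csv", index=False)

    spr_rows = []
    conc = np.geomspace(3e-9, 3.8e-6, 8)  # the measured titration span
    for i, (variant, kd, rmax) in enumerate(SPR_VARIANTS):
        c, r = simulate_binding_curve(kd, rmax, conc, noise_sd=0.01,
                                      seed=args.seed * 10 + i)
        for ci, ri in zip(c, r):
            spr_rows.append({"variant": variant, "concentration_molar": ci,
                             "response": ri})
    pd.DataFrame(spr_rows).to_csv(outdir / "spr.csv", index=False)

    truth = {
        "seed": args.seed,
        "config": {k: v for k, v in vars(cfg).items()
                   if not k.startswith("_")},
        "planted_peak_gene": peak_truth,
        "cofactor_source_index": cof_truth,
        "motif_plants": [
            {"scaffold": s, "position": p, "strand": st}
            for s, p, st in motif_truth],
        "spr_true_kd": {v: kd for v, kd, _ in SPR_VARIANTS},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))

    n_planted = sum(t is not None for t in peak_truth)
    print(f"genome: {len(genes)} genes on {cfg.n_scaffolds} scaffolds "
          f"({sum(len(s) for s in sequences.values()):,} bp)")
    print(f"primary track: {len(peaks)} peaks ({n_planted} planted at TSSs, "
          f"{len(peaks) - n_planted} background)")
    print(f"cofactor track: {len(cofactor)} peaks "
          f"({sum(t is not None for t in cof_truth)} shared)")
    print(f"motif plants: {len(motif_truth)}; "
          f"expression truth: {expression['truth'].value_counts().to_dict()}")
    print(f"wrote {outdir}/")


if __name__ == "__main__":
    main()
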