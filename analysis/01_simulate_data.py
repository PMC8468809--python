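"""Generate the synthetic study bundle with planted ground truth.

Writes, under results/data/: expression count tables for both experimental
contexts (tail-explant culture and whole animal), the truth table of planted
triad responses, a 100 kb genome (FASTA + GFF3 + BED) with CpG-enriched
intervals and planted DR/ER/IR binding motifs, methylation capture reads for
the four conditions, and the planted methylation truth.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from xtalk import io, pipeline, simulate as sim


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    explant, whole, truth = sim.simulate_expression(2000, seed=args.seed)
    io.write_counts(explant, out / "counts_explant.tsv")
    io.write_counts(whole, out / "counts_whole.tsv")
    truth.to_csv(out / "expression_truth.tsv", sep="\t", index=False)
    print(f"expression: 2000 genes x {explant.shape[1]} samples per context, "
          f"{len(truth)} with planted responses")

    rng = np.random.default_rng(args.seed + 1)
    slots = rng.choice(100_000 // 40 - 1, size=30, replace=False)
    topologies = ("DR", "IR", "ER")
    motifs = [("chr1", int(s) * 40, topologies[k % 3], int(rng.integers(0, 9)))
              for k, s in enumerate(sorted(slots))]
    genome = sim.simulate_genome(seq_len=100_000, n_dmr_intervals=8,
                                 planted_motifs=motifs, seed=args.seed + 1)
    io.write_fasta(genome.sequences, out / "genome.fa")
    io.write_gff3(genome.genes, out / "genes.gff3")
    io.write_bed(genome.tes, out / "tes.bed")
    genome.exons.to_csv(out / "exons.tsv", sep="\t", index=False)
    genome.dmr_intervals.to_csv(out / "cpg_intervals.tsv", sep="\t", index=False)
    with open(out / "planted_motifs.json", "w") as fh:
        json.dump(genome.planted_motifs, fh)
    print(f"genome: 100 kb, {len(genome.genes)} genes, {len(genome.tes)} TEs, "
          f"{len(genome.planted_motifs)} planted motifs")

    cfg = dict(pipeline.DEFAULT_CONFIG, seed=args.seed)
    truth_regions = pipeline._planted_methylation_truth(cfg, genome)
    reads = sim.simulate_methylome(100_000, truth_regions, depth=100_000,
                                   fragment_len=50, seed=args.seed + 2)
    io.write_reads_bed(reads, "chr1", out / "methylcap_reads.bed")
    with open(out / "methylation_truth.json", "w") as fh:
        json.dump(
            [
                {"start": t.start, "end": t.end, "code": t.triad_code,
                 "effects": t.effect_fraction}
                for t in truth_regions
            ],
            fh,
        )
    print(f"methylome: 4 x 100,000 reads, {len(truth_regions)} planted regions "
          f"({sum(t.direction == 'demethylation' for t in truth_regions)} demethylation)")


if __name__ == "__main__":
    main()
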