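"""Annotate called DMRs: nearest genes, TE overlap, CpG dinucleotide content."""

import argparse
from pathlib import Path

import pandas as pd

from xtalk import annotation as ann, io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    dmrs = pd.read_csv(
        args.outdir / "dmrs.bed", sep="\t", header=None,
        names=["seq_id", "start", "end", "code", "height", "sign", "category"],
    )
    genes = io.read_gff3(args.datadir / "genes.gff3")
    tes = io.read_bed(args.datadir / "tes.bed")
    sequences = io.read_fasta(args.datadir / "genome.fa")

    annotated = ann.annotate_distances(dmrs[["seq_id", "start", "end"]], genes)
    annotated["code"] = dmrs["code"]
    annotated.to_csv(args.outdir / "dmrs_annotated.tsv", sep="\t", index=False)
    overlap = (annotated.nearest_gene_distance == 0).mean()
    print(f"{100 * overlap:.1f}% of DMRs overlap or lie within genes; "
          f"median distance {annotated.nearest_gene_distance.median():.0f} bp")

    te_frac, families = ann.overlap_fraction(
        list(zip(dmrs.start, dmrs.end)),
        [(r.start, r.end, r.family) for r in tes.itertuples(index=False)],
    )
    print(f"{100 * te_frac:.1f}% of DMRs overlap transposable elements "
          f"(families: {families})")

    exons = pd.read_csv(args.datadir / "exons.tsv", sep="\t")
    dmr_prof = ann.dinucleotide_profile(
        ann.extract_sequences(sequences, dmrs[["seq_id", "start", "end"]])
    )
    exon_prof = ann.dinucleotide_profile(
        ann.extract_sequences(sequences, exons[["seq_id", "start", "end"]])
    )
    cpg = ann.cpg_enrichment(dmr_prof, exon_prof)
    pd.DataFrame({"dmr": dmr_prof, "exon": exon_prof}).to_csv(
        args.outdir / "dinucleotide_profiles.tsv", sep="\t"
    )
    print(f"CpG frequency: DMRs {cpg['cg_freq_dmr']:.3f} vs exons "
          f"{cpg['cg_freq_exon']:.3f} (ratio {cpg['cg_ratio']:.2f})")


if __name__ == "__main__":
    main()
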