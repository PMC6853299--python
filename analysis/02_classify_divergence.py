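#!/usr/bin/env python
"""Classify cis/trans regulatory divergence on the simulated experiment.

Reads the tables written by 01_simulate_dataset.py, recovers ss-SNPs from
the genotype panel, applies the detectability and ASE-eligibility filters,
then runs both classifiers: the cross-replicate 70-combination consensus
and the standard averaged-ASE method.  Writes per-gene calls, the
truth-vs-call confusion matrices and per-category recovery rates.
"""

from pathlib import Path

import pandas as pd

from hybridreg import divergence, expression, io
from hybridreg.alleles import identify_ss_snps

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    arch = io.read_tsv(OUT / "truth_architecture.tsv")
    parental = io.read_tsv(OUT / "parental_counts.tsv")
    f1 = io.read_tsv(OUT / "f1_counts.tsv")
    allele_counts = io.read_allele_counts(OUT / "allele_counts.tsv")
    lengths = io.read_tsv(OUT / "gene_lengths.tsv")["length_bp"]
    libs = io.read_tsv(OUT / "library_sizes.tsv")["library_size"]

    g1 = io.read_genotype_table(OUT / "genotypes_zf.tsv")
    g2 = io.read_genotype_table(OUT / "genotypes_of.tsv")
    snps, report = identify_ss_snps(g1, g2)
    print(f"ss-SNP recovery from genotypes: {len(snps)} sites "
          f"({report['status'].value_counts().to_dict()})")

    counts = pd.concat([parental, f1], axis=1)
    groups = pd.Series({c: c.split("_")[0] for c in counts.columns})
    expr = expression.rpkm(counts, lengths, libs)
    detectable = expression.filter_detectable(expr, groups)
    eligible, _ = expression.filter_ase_eligible(allele_counts,
                                                 expr.loc[detectable])
    print(f"{len(detectable)} detectable genes, {len(eligible)} ASE-eligible")

    y = expression.allelic_log_ratios(allele_counts).loc[eligible]
    x = expression.parental_log_ratio(expr.loc[eligible], groups)
    par = expression.parental_pairwise_ratios(expr.loc[eligible], groups)

    calls = divergence.classify_consensus(y, par, x=x)
    io.write_tsv(calls, OUT / "regulatory_calls_cross_replicate.tsv")
    std = divergence.standard_classify(y, par)
    io.write_tsv(std.to_frame(), OUT / "regulatory_calls_standard.tsv")

    truth = arch.loc[eligible, "category"]
    for name, final in (("cross-replicate", calls["final"]),
                        ("standard", std)):
        confusion = pd.crosstab(truth, final, rownames=["truth"],
                                colnames=["call"])
        io.write_tsv(confusion, OUT / f"confusion_{name.replace('-', '_')}.tsv")
        rec = {c: round(float((final[truth == c] == c).mean()), 3)
               for c in divergence.CATEGORIES}
        print(f"{name} recovery by true category: {rec}")


if __name__ == "__main__":
    main()
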