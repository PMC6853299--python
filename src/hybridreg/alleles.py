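"""Species-specific SNP identification and allele-resolved read counting.

An ss-SNP (species-specific SNP) is a site at which every individual of
one species carries one base and every individual of the other species a
different base.  At such sites, reads from an F1 hybrid can be assigned
to the parental allele they were transcribed from, which is what makes
allele-specific expression measurable.

Coordinates are 0-based half-open internally; VCF-style 1-based
positions appear only at I/O boundaries (see :mod:`hybridreg.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_VALID = frozenset("ACGT")
MISSING = frozenset({"N", ".", ""})


@dataclass(frozen=True)
class SsSnpRecord:
    """A fixed between-species difference: chrom, 0-based pos, both alleles."""
    chrom: str
    pos: int  # 0-based
    allele_sp1: str
    allele_sp2: str

    def __post_init__(self):
        if self.allele_sp1 == self.allele_sp2:
            raise ValueError("ss-SNP alleles must differ")
        for a in (self.allele_sp1, self.allele_sp2):
            if a not in _VALID:
                raise ValueError(f"invalid base {a!r}")


@dataclass
class ReadObservation:
    """Desk-scale stand-in for a mapped read: the ss-SNP sites it covers
    and the base observed at each."""
    gene: str
    individual: str
    covered_sites: Sequence[tuple[str, int]]  # (chrom, 0-based pos)
    observed_bases: Sequence[str]

    def __post_init__(self):
        if len(self.covered_sites) != len(self.observed_bases):
            raise ValueError("covered_sites and observed_bases differ in length")


class AlleleCountTable:
    """Per gene x F1 individual x ss-SNP site allele read counts.

    Wraps a long-format frame with columns
    ``gene, individual, chrom, pos, count_sp1, count_sp2``; the per-gene
    totals a = sum(count_sp1) and b = sum(count_sp2) follow per-site
    counting (a read covering several sites contributes at each).
    """

    COLUMNS = ["gene", "individual", "chrom", "pos", "count_sp1", "count_sp2"]

    def __init__(self, table: pd.DataFrame, unassigned: int = 0):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        if len(table) and ((table["count_sp1"] < 0).any()
                           or (table["count_sp2"] < 0).any()):
            raise ValueError("allele counts must be non-negative")
        self.table = table[self.COLUMNS].reset_index(drop=True)
        self.unassigned = unassigned

    def __len__(self):
        return len(self.table)

    def per_gene_totals(self) -> pd.DataFrame:
        """a, b summed over sites, indexed by (gene, individual)."""
        g = (self.table.groupby(["gene", "individual"])[
            ["count_sp1", "count_sp2"]].sum())
        return g.rename(columns={"count_sp1": "a", "count_sp2": "b"})

    def a_matrix(self) -> pd.DataFrame:
        """Species-1 allele totals as a genes x individuals frame."""
        return (self.per_gene_totals()["a"].unstack("individual")
                .fillna(0.0))

    def b_matrix(self) -> pd.DataFrame:
        return (self.per_gene_totals()["b"].unstack("individual")
                .fillna(0.0))

    def site_depths(self) -> pd.Series:
        """Total reads per (gene, individual, site)."""
        t = self.table
        return (t["count_sp1"] + t["count_sp2"]).groupby(
            [t["gene"], t["individual"], t["chrom"], t["pos"]]).sum()

    def n_sites_per_gene(self) -> pd.Series:
        return (self.table.groupby("gene")[["chrom", "pos"]]
                .apply(lambda d: d.drop_duplicates().shape[0])
                .rename("n_sites"))


# ---------------------------------------------------------------------------
# ss-SNP identification
# ---------------------------------------------------------------------------

def _fixed_base(calls: np.ndarray) -> str | None:
    """The single base fixed across non-missing calls, or None."""
    observed = {c for c in calls if c not in MISSING}
    if len(observed) == 1:
        return next(iter(observed))
    return None


def identify_ss_snps(genotypes_sp1: pd.DataFrame,
                     genotypes_sp2: pd.DataFrame
                     ) -> tuple[list[SsSnpRecord], pd.DataFrame]:
    """Find sites fixed within each species and divergent between them.

    Both frames must be indexed by (chrom, pos) with 1-based positions
    (the tabular/VCF convention) and hold one base call per individual;
    missing calls ('N', '.', '') are ignored, but a site needs at least
    one non-missing call per species.  Sites with any within-species
    disagreement are excluded and reported as intraspecies SNPs.

    Returns the ss-SNP records (0-based positions) and a per-site status
    frame with ``status`` in {ss_snp, intraspecies, monomorphic,
    missing}.
    """
    common = genotypes_sp1.index.intersection(genotypes_sp2.index)
    if len(common) == 0:
        raise ValueError("genotype matrices share no sites")
    g1 = genotypes_sp1.loc[common]
    g2 = genotypes_sp2.loc[common]

    records: list[SsSnpRecord] = []
    status = []
    for (chrom, pos), row1, row2 in zip(common, g1.to_numpy(), g2.to_numpy()):
        b1 = _fixed_base(row1)
        b2 = _fixed_base(row2)
        all_missing = (all(c in MISSING for c in row1)
                       or all(c in MISSING for c in row2))
        if all_missing:
            status.append("missing")
        elif b1 is None or b2 is None:
            status.append("intraspecies")
        elif b1 != b2:
            records.append(SsSnpRecord(chrom, int(pos) - 1, b1, b2))
            status.append("ss_snp")
        else:
            status.append("monomorphic")
    report = pd.DataFrame({"status": status}, index=common)
    return records, report


def mask_reference(reference: str, snps: Iterable[SsSnpRecord]) -> str:
    """Replace the base at each ss-SNP position with 'N' (N-masked genome).

    Masking removes the reference allele from the sequence so alignment
    cannot favour the reference species at these sites.
    """
    seq = list(reference)
    for snp in snps:
        if not 0 <= snp.pos < len(seq):
            raise ValueError(
                f"position {snp.pos} outside sequence of length {len(seq)}")
        seq[snp.pos] = "N"
    return "".join(seq)


def validate_ss_snp_purity(snp: SsSnpRecord,
                           pileup_sp1: Mapping[str, int],
                           pileup_sp2: Mapping[str, int],
                           threshold: float = 0.98) -> bool:
    """Keep an ss-SNP only if parental reads overwhelmingly support it.

    The fraction of parental reads carrying their own species' expected
    allele must exceed ``threshold`` (default 0.98) of the total reads at
    the site.  Zero coverage drops the site with a warning.
    """
    total = sum(pileup_sp1.values()) + sum(pileup_sp2.values())
    if total == 0:
        warnings.warn(f"no parental coverage at {snp.chrom}:{snp.pos + 1}; "
                      "dropping site")
        return False
    concordant = (pileup_sp1.get(snp.allele_sp1, 0)
                  + pileup_sp2.get(snp.allele_sp2, 0))
    return concordant / total > threshold


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------

def assign_reads(reads: Iterable[ReadObservation],
                 snps: Iterable[SsSnpRecord],
                 counting: str = "per-site") -> AlleleCountTable:
    """Attribute F1 read observations to parental alleles at ss-SNP sites.

    ``counting='per-site'`` (default): each covered site contributes one
    count to whichever allele its observed base matches, so a read
    spanning several ss-SNPs counts at each of them.
    ``counting='per-read'``: a majority vote over the read's sites adds a
    single count (at the read's first site); ties are unassigned.
    Bases matching neither allele are tallied in ``unassigned``.
    """
    if counting not in ("per-site", "per-read"):
        raise ValueError(f"unknown counting mode {counting!r}")
    lookup = {(s.chrom, s.pos): s for s in snps}
    counts: dict[tuple, list[int]] = {}
    unassigned = 0

    def bump(gene, ind, chrom, pos, which):
        key = (gene, ind, chrom, pos)
        if key not in counts:
            counts[key] = [0, 0]
        counts[key][which] += 1

    for read in reads:
        votes = []
        for (chrom, pos), base in zip(read.covered_sites,
                                      read.observed_bases):
            snp = lookup.get((chrom, pos))
            if snp is None:
                raise KeyError(f"site {chrom}:{pos} is not a retained ss-SNP")
            if base == snp.allele_sp1:
                votes.append(((chrom, pos), 0))
            elif base == snp.allele_sp2:
                votes.append(((chrom, pos), 1))
            else:
                votes.append(((chrom, pos), None))
        if counting == "per-site":
            for (chrom, pos), which in votes:
                if which is None:
                    unassigned += 1
                else:
                    bump(read.gene, read.individual, chrom, pos, which)
        else:
            tally = [sum(1 for _, w in votes if w == 0),
                     sum(1 for _, w in votes if w == 1)]
            if tally[0] == tally[1]:
                unassigned += 1
            else:
                chrom, pos = read.covered_sites[0]
                bump(read.gene, read.individual, chrom, pos,
                     0 if tally[0] > tally[1] else 1)

    rows = [(g, i, c, p, v[0], v[1])
            for (g, i, c, p), v in sorted(counts.items())]
    table = pd.DataFrame(rows, columns=AlleleCountTable.COLUMNS)
    return AlleleCountTable(table, unassigned=unassigned)
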