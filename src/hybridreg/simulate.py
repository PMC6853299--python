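"""Synthetic parental / F1-hybrid expression data and songs with known truth.

The generator emulates the study design the analysis assumes: four
parental individuals per species (ZF, OF), eight F1 hybrids in two
reciprocal crosses (4 ZO + 4 OZ), gene-wise negative-binomial read
counts with additive log2 cis (c) and trans (t) effects, and binomially
split allele reads at species-specific SNP (ss-SNP) sites.

Model
-----
For a gene with baseline expected count mu:

* species-1 parental mean = mu * 2**(c + t), species-2 mean = mu, so the
  true parental log2 ratio is X = c + t;
* in F1 hybrids both alleles share one trans environment, so species-1
  allele reads at each ss-SNP site are Binomial(depth, 2**c / (1 + 2**c))
  and the true allelic log2 ratio is Y = c;
* F1 total expression sits at the mid-parent trans environment,
  mu * (1 + 2**c)/2 * 2**(t/2).

Reciprocal-cross labels (ZO / OZ) are recorded but draw from identical
distributions: the model contains no genomic imprinting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .alleles import AlleleCountTable
from .divergence import CATEGORIES

DistSpec = float | int | tuple | Callable[[np.random.Generator, int], np.ndarray]

#: default category mix: observed per-category rates among eligible genes in
#: songbird song-nucleus tissue (a few percent each of cis, trans and both,
#: the rest conserved)
DEFAULT_PROPORTIONS = {
    "cis": 0.027,
    "trans": 0.047,
    "cis_and_trans": 0.031,
    "conserved": 0.895,
}


def draw(spec: DistSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw ``size`` values from a distribution spec.

    A number is a constant; ``("lognormal", mu, sigma)``,
    ``("uniform", lo, hi)`` and ``("poisson", lam)`` name parametric
    families; a callable is invoked as ``spec(rng, size)``.
    """
    if callable(spec):
        return np.asarray(spec(rng, size))
    if isinstance(spec, (int, float)):
        return np.full(size, float(spec))
    name, *params = spec
    if name == "lognormal":
        return rng.lognormal(params[0], params[1], size)
    if name == "uniform":
        return rng.uniform(params[0], params[1], size)
    if name == "poisson":
        return rng.poisson(params[0], size).astype(float)
    raise ValueError(f"unknown distribution spec {spec!r}")


@dataclass
class SimulationConfig:
    """Conditions of a synthetic experiment.

    Defaults follow the study design: 4 parental individuals per species,
    8 F1 hybrids (4 ZO + 4 OZ), effect magnitudes of 2 log2 units with
    random sign, 4 ss-SNP sites per gene at 50 reads per site, a shared
    negative-binomial dispersion of 0.05 (typical bulk-RNA-seq biological
    variability at n = 4), 1 kb genes and 1e6 mapped reads per library.
    """
    n_genes: int = 1000
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    cis_effect_dist: DistSpec = 2.0     # |c| in log2 units; sign randomised
    trans_effect_dist: DistSpec = 2.0   # |t| in log2 units; sign randomised
    baseline_mean_dist: DistSpec = ("lognormal", math.log(200.0), 1.0)
    nb_dispersion: float = 0.05
    n_parental_per_species: int = 4
    n_f1: int = 8
    snps_per_gene_dist: DistSpec = 4
    per_snp_depth_dist: DistSpec = 50
    intraspecies_poly_rate: float = 0.1
    gene_length_bp: int = 1000
    library_size: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"class_proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_f1 % 2:
            raise ValueError("n_f1 must be even (reciprocal crosses)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def parental_ids(self) -> list[str]:
        n = self.n_parental_per_species
        return ([f"ZF_{i + 1}" for i in range(n)]
                + [f"OF_{i + 1}" for i in range(n)])

    @property
    def f1_ids(self) -> list[str]:
        h = self.n_f1 // 2
        return ([f"ZO_{i + 1}" for i in range(h)]
                + [f"OZ_{i + 1}" for i in range(h)])

    @property
    def groups(self) -> pd.Series:
        labels = {}
        for ind in self.parental_ids + self.f1_ids:
            labels[ind] = ind.split("_")[0]
        return pd.Series(labels, name="group")


# ---------------------------------------------------------------------------
# Regulatory architecture
# ---------------------------------------------------------------------------

def simulate_architecture(config: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Draw the true regulatory architecture: per-gene category and effects.

    Categories are i.i.d. from ``class_proportions``.  Effect magnitudes
    come from the configured distributions with random sign; the category
    constraints (cis => t = 0, trans => c = 0, conserved => c = t = 0)
    are enforced exactly.
    """
    rng = config.rng() if rng is None else rng
    cats = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in cats])
    category = rng.choice(cats, size=config.n_genes, p=probs)

    c = draw(config.cis_effect_dist, rng, config.n_genes)
    t = draw(config.trans_effect_dist, rng, config.n_genes)
    c = c * rng.choice([-1.0, 1.0], size=config.n_genes)
    t = t * rng.choice([-1.0, 1.0], size=config.n_genes)

    has_cis = np.isin(category, ["cis", "cis_and_trans"])
    has_trans = np.isin(category, ["trans", "cis_and_trans"])
    c = np.where(has_cis, c, 0.0)
    t = np.where(has_trans, t, 0.0)

    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    return pd.DataFrame(
        {"category": category, "cis_effect": c, "trans_effect": t},
        index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with var = mean + dispersion * mean**2;
    collapses to Poisson at dispersion -> 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


@dataclass
class SimulatedCounts:
    """Bundle of all count tables from one simulated experiment."""
    parental_counts: pd.DataFrame   # genes x parental individuals
    f1_counts: pd.DataFrame         # genes x F1 individuals
    allele_counts: "AlleleCountTable"
    groups: pd.Series               # individual -> {ZF, OF, ZO, OZ}
    gene_lengths: pd.Series
    library_sizes: pd.Series


def simulate_counts(arch: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> SimulatedCounts:
    """Simulate parental counts, F1 total counts and per-site allele counts."""
    rng = config.rng() if rng is None else rng
    genes = arch.index
    n = len(genes)
    mu = draw(config.baseline_mean_dist, rng, n)
    c = arch["cis_effect"].to_numpy()
    t = arch["trans_effect"].to_numpy()

    mean_sp1 = mu * 2.0 ** (c + t)
    mean_sp2 = mu
    npar = config.n_parental_per_species
    par = {}
    for i in range(npar):
        par[f"ZF_{i + 1}"] = _nb_draw(rng, mean_sp1, config.nb_dispersion)
    for i in range(npar):
        par[f"OF_{i + 1}"] = _nb_draw(rng, mean_sp2, config.nb_dispersion)
    parental = pd.DataFrame(par, index=genes)

    # F1 totals: both alleles in one (mid-parent) trans environment
    mean_f1 = mu * (1.0 + 2.0 ** c) / 2.0 * 2.0 ** (t / 2.0)
    f1 = {ind: _nb_draw(rng, mean_f1, config.nb_dispersion)
          for ind in config.f1_ids}
    f1_counts = pd.DataFrame(f1, index=genes)

    # allele reads at ss-SNP sites, binomially split by the cis effect
    q = 2.0 ** c / (1.0 + 2.0 ** c)
    n_sites = np.maximum(
        np.rint(draw(config.snps_per_gene_dist, rng, n)).astype(int), 0)
    rows = []
    for gi, gene in enumerate(genes):
        for site in range(n_sites[gi]):
            pos = gi * 10_000 + site * 100 + 1  # synthetic coordinates
            for ind in config.f1_ids:
                depth = int(round(float(draw(config.per_snp_depth_dist,
                                             rng, 1)[0])))
                k1 = int(rng.binomial(depth, q[gi])) if depth > 0 else 0
                rows.append((gene, ind, "chr1", pos, k1, depth - k1))
    table = pd.DataFrame(
        rows, columns=["gene", "individual", "chrom", "pos",
                       "count_sp1", "count_sp2"])
    allele_counts = AlleleCountTable(table)

    lengths = pd.Series(config.gene_length_bp, index=genes,
                        name="length_bp", dtype=float)
    all_counts = pd.concat([parental, f1_counts], axis=1)
    # library size fixed by design; per-gene counts are small against it
    lib = pd.Series(config.library_size, index=all_counts.columns,
                    name="library_size", dtype=float)
    return SimulatedCounts(parental, f1_counts, allele_counts,
                           config.groups, lengths, lib)


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[pd.DataFrame, SimulatedCounts]:
    """Architecture + counts from a single seeded stream."""
    rng = config.rng()
    arch = simulate_architecture(config, rng)
    return arch, simulate_counts(arch, config, rng)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_genotypes(config: SimulationConfig, n_sites: int = 1000,
                       divergent_fraction: float = 0.5,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Site x individual base calls for both species, with truth labels.

    Each site is divergent between the species with probability
    ``divergent_fraction``; a divergent site becomes a true ss-SNP unless
    an intraspecies polymorphism (rate ``intraspecies_poly_rate``) breaks
    within-species fixation.  Non-divergent sites are monomorphic.

    Returns ``(genotypes_sp1, genotypes_sp2, truth)`` where the genotype
    frames are indexed by (chrom, pos) with one column per individual,
    and ``truth`` carries columns ``label`` in {ss_snp, intraspecies,
    monomorphic}, ``allele_sp1`` and ``allele_sp2``.
    """
    rng = config.rng() if rng is None else rng
    npar = config.n_parental_per_species
    sp1_ids = [f"ZF_{i + 1}" for i in range(npar)]
    sp2_ids = [f"OF_{i + 1}" for i in range(npar)]
    index = pd.MultiIndex.from_arrays(
        [np.repeat("chr1", n_sites), np.arange(1, n_sites + 1)],
        names=["chrom", "pos"])

    base1 = rng.choice(_BASES, size=n_sites)
    divergent = rng.random(n_sites) < divergent_fraction
    # pick a different base for species 2 at divergent sites
    shift = rng.integers(1, 4, size=n_sites)
    idx1 = np.searchsorted(_BASES, base1)
    base2 = np.where(divergent, _BASES[(idx1 + shift) % 4], base1)

    g1 = np.tile(base1[:, None], (1, npar)).astype(object)
    g2 = np.tile(base2[:, None], (1, npar)).astype(object)

    poly = divergent & (rng.random(n_sites) < config.intraspecies_poly_rate)
    labels = np.where(~divergent, "monomorphic",
                      np.where(poly, "intraspecies", "ss_snp"))
    # break fixation at polymorphic sites: one individual in one species
    # carries the other species' base
    which_sp = rng.integers(0, 2, size=n_sites)
    which_ind = rng.integers(0, npar, size=n_sites)
    for i in np.flatnonzero(poly):
        if which_sp[i] == 0:
            g1[i, which_ind[i]] = base2[i]
        else:
            g2[i, which_ind[i]] = base1[i]

    truth = pd.DataFrame({"label": labels, "allele_sp1": base1,
                          "allele_sp2": base2}, index=index)
    return (pd.DataFrame(g1, index=index, columns=sp1_ids),
            pd.DataFrame(g2, index=index, columns=sp2_ids),
            truth)


# ---------------------------------------------------------------------------
# Songs
# ---------------------------------------------------------------------------

@dataclass
class SongConfig:
    """Grammar and acoustics of a synthetic song.

    ``grammar`` is one of:

    * ``"motif"`` — a fixed sequence of ``n_types`` distinct syllable
      types repeated (ABCD ABCD ...);
    * ``"repetition"`` — runs of a single type (AAAA ...);
    * ``"mixture"`` — a Markov walk that advances along the motif cycle
      with probability ``p_motif`` and otherwise repeats the current
      syllable.
    """
    grammar: str = "motif"
    n_types: int = 4
    n_syllables: int = 24
    p_motif: float = 0.5
    noise_sd: float = 0.0
    n_frames: int = 20
    n_features: int = 10
    syllable_s: float = 0.08
    gap_s: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if self.grammar not in ("motif", "repetition", "mixture"):
            raise ValueError(f"unknown grammar {self.grammar!r}")
        if self.grammar == "motif" and self.n_types < 2:
            raise ValueError("motif grammar requires at least 2 types")


@dataclass
class SongRecord:
    """A simulated song: syllable type sequence plus feature trajectories."""
    sequence: list[str]
    trajectories: list[np.ndarray]  # each (n_frames, n_features)
    grammar: str
    onsets_s: np.ndarray | None = None
    offsets_s: np.ndarray | None = None


def _type_centroids(cfg: SongConfig, rng: np.random.Generator) -> np.ndarray:
    """Mutually decorrelated centroid trajectory per syllable type.

    Centroids are orthogonalised after mean-centering so that, at zero
    noise, different types have Pearson correlation 0 (similarity 0.5 on
    the [0, 1] scale) and identical types correlate perfectly."""
    k = cfg.n_types
    dim = cfg.n_frames * cfg.n_features
    flat = rng.normal(0.0, 1.0, size=(k, dim))
    flat -= flat.mean(axis=1, keepdims=True)
    # Gram-Schmidt on the mean-centered rows keeps them mean-centered
    for i in range(k):
        for j in range(i):
            flat[i] -= (flat[i] @ flat[j]) / (flat[j] @ flat[j]) * flat[j]
        flat[i] /= np.linalg.norm(flat[i])
    return (flat * np.sqrt(dim)).reshape(k, cfg.n_frames, cfg.n_features)


def _sequence(cfg: SongConfig, rng: np.random.Generator) -> list[int]:
    if cfg.grammar == "motif":
        return [i % cfg.n_types for i in range(cfg.n_syllables)]
    if cfg.grammar == "repetition":
        return [0] * cfg.n_syllables
    seq = [0]
    for _ in range(cfg.n_syllables - 1):
        if rng.random() < cfg.p_motif:
            seq.append((seq[-1] + 1) % cfg.n_types)
        else:
            seq.append(seq[-1])
    return seq


def simulate_songs(cfg: SongConfig, n_songs: int = 1) -> list[SongRecord]:
    """Generate songs with known grammar; type labels are 'A', 'B', ..."""
    rng = np.random.default_rng(cfg.seed)
    centroids = _type_centroids(cfg, rng)
    songs = []
    for _ in range(n_songs):
        types = _sequence(cfg, rng)
        trajs = [centroids[t]
                 + rng.normal(0.0, cfg.noise_sd,
                              size=(cfg.n_frames, cfg.n_features))
                 for t in types]
        onsets = np.arange(len(types)) * (cfg.syllable_s + cfg.gap_s)
        offsets = onsets + cfg.syllable_s
        songs.append(SongRecord(
            sequence=[chr(ord("A") + t) for t in types],
            trajectories=trajs, grammar=cfg.grammar,
            onsets_s=onsets, offsets_s=offsets))
    return songs


def synthesize_waveform(record: SongRecord, cfg: SongConfig,
                        sample_rate: int = 44_100,
                        f0_base: float = 600.0,
                        n_harmonics: int = 5) -> np.ndarray:
    """Render a song as mono audio: one harmonic stack per syllable type.

    Each type gets a distinct fundamental; harmonics decay as 1/h.  A
    10 ms cosine ramp at the edges avoids clicks.  Intended for testing
    segmentation and acoustic-feature extraction, not for realism.
    """
    syl_n = int(cfg.syllable_s * sample_rate)
    gap_n = int(cfg.gap_s * sample_rate)
    total = len(record.sequence) * (syl_n + gap_n)
    wave = np.zeros(total)
    t = np.arange(syl_n) / sample_rate
    ramp_n = max(int(0.01 * sample_rate), 1)
    env = np.ones(syl_n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    env[:ramp_n] = ramp
    env[-ramp_n:] = ramp[::-1]
    for i, label in enumerate(record.sequence):
        tidx = ord(label) - ord("A")
        f0 = f0_base * (1.0 + 0.5 * tidx)
        tone = sum(np.sin(2 * np.pi * f0 * h * t) / h
                   for h in range(1, n_harmonics + 1))
        start = i * (syl_n + gap_n)
        wave[start:start + syl_n] = env * tone / np.abs(tone).max()
    return wave
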