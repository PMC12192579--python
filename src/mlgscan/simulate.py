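"""Synthetic diploid genotypes with local LD and injected anomalies.

The simulator is deliberately simple: per-site alternate-allele
frequencies are drawn from a uniform law, and each of the two
pseudo-haplotypes per individual is generated left-to-right with a
first-order copying process — with probability ``rho`` a site copies the
previous site's allelic state on the same haplotype, otherwise it draws
Bernoulli(f_site) fresh.  This produces enough genotype autocorrelation
to exercise the FDA features without modeling recombination maps,
demography or coalescent genealogies.

Injected anomalies emulate the signals a scan should flag: an
excess-heterozygosity region (balancing-selection-like), a collapse of
the local MLG spectrum to two haplotype-like strings, and a
dropout-style artifact forcing a subset of individuals to homozygous
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix

ANOMALY_KINDS = ("excess_het", "freq_collapse", "dropout_artifact")


@dataclass
class SimulationConfig:
    """Parameters of one simulated chromosome.

    ``rho`` is the per-site probability that a haplotype copies its left
    neighbor's allele (first-order LD persistence); 0.5 is the package's
    realistic default for desk-scale pipeline checks.  ``f_min``/``f_max``
    bound the uniform allele-frequency law.  ``mean_spacing`` controls
    the (random, strictly positive) base-pair gaps between SNPs.
    """

    n: int = 60
    L: int = 6000
    f_min: float = 0.05
    f_max: float = 0.95
    rho: float = 0.5
    seed: int = 0
    chrom: str = "chr1"
    mean_spacing: int = 500

    def __post_init__(self) -> None:
        if self.n < 2 or self.L < 1:
            raise ValueError("need n >= 2 individuals and L >= 1 SNPs")
        if not (0.0 <= self.f_min <= self.f_max <= 1.0):
            raise ValueError("need 0 <= f_min <= f_max <= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("need 0 <= rho < 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate an n x L genotype matrix of alternate-allele counts."""
    rng = np.random.default_rng(config.seed)
    n, L = config.n, config.L
    freqs = rng.uniform(config.f_min, config.f_max, L)
    fresh = (rng.random((n, 2, L)) < freqs).astype(np.int8)
    copy = rng.random((n, 2, L)) < config.rho
    hap = np.empty((n, 2, L), dtype=np.int8)
    hap[:, :, 0] = fresh[:, :, 0]
    for t in range(1, L):
        hap[:, :, t] = np.where(copy[:, :, t], hap[:, :, t - 1], fresh[:, :, t])
    gaps = rng.integers(1, 2 * config.mean_spacing, size=L)
    positions = np.cumsum(gaps)
    return GenotypeMatrix(
        chrom=config.chrom,
        positions=positions,
        G=hap.sum(axis=1),
        sample_ids=[f"ind{i}" for i in range(n)],
    )


def inject_anomaly(
    gm: GenotypeMatrix,
    span: tuple[int, int],
    kind: str,
    seed: int = 0,
) -> GenotypeMatrix:
    """Return a copy of ``gm`` with an anomaly over SNP columns [start, stop).

    Kinds:

    * ``excess_het`` — genotypes in the span resampled with heterozygote
      probability 0.9 (0.05 each homozygote).
    * ``freq_collapse`` — every individual set to one of two fixed MLG
      strings across the span, at frequencies 0.5/0.5.
    * ``dropout_artifact`` — a random 30% of individuals set homozygous
      reference across the span.

    Entries outside the span are untouched.
    """
    start, stop = span
    n, L = gm.G.shape
    if not (0 <= start < stop <= L):
        raise ValueError(f"span {span} out of bounds for L={L}")
    if kind not in ANOMALY_KINDS:
        raise ValueError(f"unknown anomaly kind {kind!r}; choose from {ANOMALY_KINDS}")
    rng = np.random.default_rng(seed)
    G = gm.G.copy()
    width = stop - start
    if kind == "excess_het":
        G[:, start:stop] = rng.choice(
            [0, 1, 2], size=(n, width), p=[0.05, 0.9, 0.05]
        )
    elif kind == "freq_collapse":
        strings = rng.integers(0, 3, size=(2, width))
        G[:, start:stop] = strings[np.arange(n) % 2]
    else:  # dropout_artifact
        k = max(1, int(round(0.3 * n)))
        rows = rng.choice(n, size=k, replace=False)
        G[rows, start:stop] = 0
    return GenotypeMatrix(
        chrom=gm.chrom,
        positions=gm.positions.copy(),
        G=G,
        sample_ids=list(gm.sample_ids),
    )


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal valid VCF 4.2 that round-trips through the loader.

    Genotypes 0/1/2 become 0/0, 0/1, 1/1; internal 0-based positions are
    written 1-based per the VCF convention.  REF/ALT are fixed A/G.
    """
    code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gm.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, pos in enumerate(gm.positions):
            gts = "\t".join(code[int(g)] for g in gm.G[:, j])
            fh.write(f"{gm.chrom}\t{pos + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
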