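"""Genotype matrices and sliding SNP windows.

Unphased diploid genotypes at biallelic SNPs are encoded per individual as
the number of alternate alleles, 0/1/2, and held as an ``n x L`` integer
matrix per chromosome.  All downstream statistics operate on fixed-width
windows of ``l`` contiguous SNP columns shifted by one SNP.

Coordinates are 0-based half-open throughout the package (BED convention);
VCF positions are converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_SNP_ALLELES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Per-chromosome matrix of alternate-allele counts.

    Attributes
    ----------
    chrom
        Chromosome identifier.
    positions
        Length-``L`` vector of strictly increasing 0-based coordinates.
    G
        ``n x L`` integer matrix with entries in ``{0, 1, 2}``.
    sample_ids
        ``n`` sample labels, in VCF column order (row order is preserved
        end-to-end).
    """

    chrom: str
    positions: np.ndarray
    G: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.G = np.asarray(self.G)
        if self.G.ndim != 2:
            raise ValueError("G must be a 2-D matrix")
        n, L = self.G.shape
        if n < 2:
            raise ValueError(f"need at least 2 individuals, got {n}")
        if L < 1:
            raise ValueError("need at least one SNP")
        if self.positions.shape != (L,):
            raise ValueError("positions length must match number of SNP columns")
        if L > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        vals = np.unique(self.G)
        if not np.isin(vals, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")
        if not self.sample_ids:
            self.sample_ids = [f"sample{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match number of rows")

    @property
    def n_individuals(self) -> int:
        return self.G.shape[0]

    @property
    def n_snps(self) -> int:
        return self.G.shape[1]


@dataclass
class SnpWindow:
    """A contiguous ``n x l`` genotype submatrix.

    ``start_index`` is 0-based into the parent matrix's SNP columns;
    ``center_position`` is the coordinate of the middle SNP (``l`` odd).
    """

    chrom: str
    start_index: int
    Gjk: np.ndarray
    center_position: int


def load_biallelic_genotypes(vcf_path: str, chrom: str) -> GenotypeMatrix:
    """Read one chromosome of biallelic SNP genotypes from a VCF.

    Sites are kept only if they have exactly one REF and one ALT allele,
    both single nucleotides.  Genotypes are encoded as the count of ALT
    alleles regardless of phase.  Any site with one or more missing calls
    is dropped (logged); this keeps every window a complete {0,1,2} matrix.

    Parameters
    ----------
    vcf_path
        Path to a VCF 4.x file (plain or gzip/bgzip compressed).
    chrom
        Chromosome to extract.

    Raises
    ------
    ValueError
        If no biallelic SNP with complete calls is found on ``chrom``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = list(vcf.samples)
    positions: list[int] = []
    columns: list[np.ndarray] = []
    n_missing_dropped = 0
    for variant in vcf:
        if variant.CHROM != chrom:
            continue
        if len(variant.ALT) != 1:
            continue
        if variant.REF not in _SNP_ALLELES or variant.ALT[0] not in _SNP_ALLELES:
            continue
        gts = variant.gt_types  # gts012: 0/1/2 = ALT count, 3 = missing
        if np.any(gts == 3):
            n_missing_dropped += 1
            continue
        positions.append(variant.start)  # 0-based
        columns.append(gts.astype(np.int8))
    vcf.close()
    if n_missing_dropped:
        logger.info(
            "dropped %d site(s) with missing calls on %s", n_missing_dropped, chrom
        )
    if not columns:
        raise ValueError(f"no complete biallelic SNPs found on chromosome {chrom!r}")
    pos = np.asarray(positions, dtype=np.int64)
    G = np.column_stack(columns)
    order = np.argsort(pos, kind="stable")
    return GenotypeMatrix(
        chrom=chrom, positions=pos[order], G=G[:, order], sample_ids=sample_ids
    )


def list_chromosomes(vcf_path: str) -> list[str]:
    """Chromosome identifiers present in a VCF, in order of first appearance."""
    from cyvcf2 import VCF

    seen: dict[str, None] = {}
    vcf = VCF(str(vcf_path))
    for variant in vcf:
        seen.setdefault(variant.CHROM, None)
    vcf.close()
    return list(seen)


def iter_snp_windows(
    gm: GenotypeMatrix, window_size: int, stride: int = 1
) -> Iterator[SnpWindow]:
    """Yield sliding windows of ``window_size`` contiguous SNPs.

    At stride 1 there are ``L - window_size + 1`` windows.  ``window_size``
    must be odd so each window has a unique center SNP, whose coordinate
    anchors the window.  If ``L < window_size`` the sequence is empty and a
    warning is logged.
    """
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError("window_size must be an odd positive integer")
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    L = gm.n_snps
    if L < window_size:
        logger.warning(
            "chromosome %s has %d SNPs < window size %d: no windows",
            gm.chrom,
            L,
            window_size,
        )
        return
    half = (window_size - 1) // 2
    for k in range(0, L - window_size + 1, stride):
        yield SnpWindow(
            chrom=gm.chrom,
            start_index=k,
            Gjk=gm.G[:, k : k + window_size],
            center_position=int(gm.positions[k + half]),
        )


def write_matrix_tsv(gm: GenotypeMatrix, path: str) -> None:
    """Debug dump: rows = samples, columns = positions, tab-separated."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(str(p) for p in gm.positions) + "\n")
        for sid, row in zip(gm.sample_ids, gm.G):
            fh.write(sid + "\t" + "\t".join(str(int(g)) for g in row) + "\n")
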