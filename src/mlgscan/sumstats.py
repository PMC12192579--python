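"""Per-window summaries of multilocus-genotype (MLG) diversity.

Each l-SNP window is reduced to m = 8 statistics: the mean, variance,
skewness and kurtosis of the pairwise scaled Manhattan distances between
individuals' MLG strings, plus the frequencies of the four most common
MLGs.  These are the raw material for feature extraction.

Moment conventions (fixed package-wide): population (divide-by-count)
central moments; skewness = m3 / m2^1.5; kurtosis = excess kurtosis
m4 / m2^2 - 3; zero-variance inputs yield skewness = kurtosis = 0 so that
downstream matrices stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .genotypes import GenotypeMatrix, iter_snp_windows

#: Column order of the per-window statistic vector.
STAT_NAMES = ("mu", "var", "skew", "kurt", "f1", "f2", "f3", "f4")
N_STATS = len(STAT_NAMES)

# relative float-noise floor for the variance of distances bounded by 2
_VAR_EPS = 1e-28


@dataclass
class SummaryStatMatrix:
    """Stack of per-window statistic vectors for one chromosome.

    ``stats`` is ``(L - l + 1) x 8`` in :data:`STAT_NAMES` order; row k
    corresponds to the window starting at SNP k, anchored at
    ``center_positions[k]``.
    """

    chrom: str
    stats: np.ndarray
    center_positions: np.ndarray
    window_size: int

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        self.center_positions = np.asarray(self.center_positions, dtype=np.int64)
        if self.stats.ndim != 2 or self.stats.shape[1] != N_STATS:
            raise ValueError(f"stats must have {N_STATS} columns")
        if len(self.center_positions) != len(self.stats):
            raise ValueError("one center position per window required")

    @property
    def n_windows(self) -> int:
        return self.stats.shape[0]


def pairwise_manhattan(Gjk: np.ndarray) -> np.ndarray:
    """Pairwise Manhattan distances between MLG strings, scaled by l.

    d(i, i') = (1/l) * sum_t |g_it - g_i't| over the l SNPs of the window,
    for all n(n-1)/2 pairs in canonical upper-triangle (row-major) order.
    Values lie in [0, 2].
    """
    Gjk = np.asarray(Gjk)
    if Gjk.ndim != 2 or Gjk.shape[0] < 2:
        raise ValueError("need an n x l matrix with n >= 2")
    return pdist(Gjk.astype(float), metric="cityblock") / Gjk.shape[1]


def distance_moments(d: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, excess kurtosis) of a distance vector."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance vector")
    mu = float(d.mean())
    dev = d - mu
    m2 = float(np.mean(dev**2))
    if m2 <= _VAR_EPS * max(1.0, mu * mu):
        return mu, 0.0, 0.0, 0.0
    m3 = float(np.mean(dev**3))
    m4 = float(np.mean(dev**4))
    return mu, m2, m3 / m2**1.5, m4 / m2**2 - 3.0


def mlg_frequencies(Gjk: np.ndarray) -> tuple[float, float, float, float]:
    """Frequencies of the four most common MLGs in the window.

    An MLG is the exact l-length string of an individual's {0,1,2} values;
    identical strings define the same MLG.  Fewer than four distinct MLGs
    leave the remaining frequencies at 0.
    """
    Gjk = np.asarray(Gjk)
    if Gjk.ndim != 2 or Gjk.shape[0] < 1:
        raise ValueError("need an n x l matrix with n >= 1")
    n = Gjk.shape[0]
    _, counts = np.unique(Gjk, axis=0, return_counts=True)
    top = np.sort(counts)[::-1][:4] / n
    f = np.zeros(4)
    f[: top.size] = top
    return tuple(f)


def window_stat_vector(Gjk: np.ndarray) -> np.ndarray:
    """The 8-vector (mu, var, skew, kurt, f1..f4) for one window."""
    mu, var, skew, kurt = distance_moments(pairwise_manhattan(Gjk))
    return np.array([mu, var, skew, kurt, *mlg_frequencies(Gjk)])


def compute_stat_matrix(gm: GenotypeMatrix, window_size: int = 51) -> SummaryStatMatrix:
    """Summary-statistic matrix over all sliding windows of a chromosome."""
    rows = []
    centers = []
    for win in iter_snp_windows(gm, window_size):
        rows.append(window_stat_vector(win.Gjk))
        centers.append(win.center_position)
    if not rows:
        raise ValueError(
            f"chromosome {gm.chrom}: {gm.n_snps} SNPs < window size {window_size}"
        )
    return SummaryStatMatrix(
        chrom=gm.chrom,
        stats=np.vstack(rows),
        center_positions=np.asarray(centers),
        window_size=window_size,
    )


def write_stats_tsv(sm: SummaryStatMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# window_size={sm.window_size}\n")
        fh.write("chrom\tcenter_position\t" + "\t".join(STAT_NAMES) + "\n")
        for pos, row in zip(sm.center_positions, sm.stats):
            vals = "\t".join(format(v, ".10g") for v in row)
            fh.write(f"{sm.chrom}\t{pos}\t{vals}\n")


def read_stats_tsv(path: str) -> SummaryStatMatrix:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline().strip()
    window_size = int(header.split("window_size=")[1])
    df = pd.read_csv(path, sep="\t", skiprows=1)
    return SummaryStatMatrix(
        chrom=str(df["chrom"].iloc[0]),
        stats=df[list(STAT_NAMES)].to_numpy(),
        center_positions=df["center_position"].to_numpy(),
        window_size=window_size,
    )
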