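"""MLG-diversity images for outlier regions, and Manhattan-plot tables.

An outlier stretch is defined by w + l - 1 consecutive SNPs.  Its
diversity image re-polarizes each SNP column to minor-allele counts,
slides the l-SNP window across the region (w placements), sorts each
window's rows by L1 norm, and averages, for every individual and SNP,
the sorted entries over all windows containing that SNP.  The result is
an n x (w + l - 1) matrix with values in [0, 2]: 0 = homozygous major
allele (dark), 2 = homozygous minor allele (bright), intermediate shades
mark heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import PValueTable


@dataclass
class DiversityImage:
    """Mean sorted minor-allele counts per individual x SNP."""

    X: np.ndarray  # n x (w + l - 1), values in [0, 2]
    chrom: str = ""
    position: int = 0
    gene: str = ""


def minor_allele_matrix(G_region: np.ndarray) -> np.ndarray:
    """Re-polarize each column so the minor allele is counted.

    Columns whose mean allele count exceeds 1 are flipped g -> 2 - g;
    ties (mean exactly 1) are left unflipped.  Performed per region: the
    minor allele is defined locally, not genome-wide.
    """
    G = np.asarray(G_region)
    if not np.isin(np.unique(G), (0, 1, 2)).all():
        raise ValueError("genotype entries must be in {0, 1, 2}")
    flip = G.mean(axis=0) > 1.0
    out = G.copy()
    out[:, flip] = 2 - out[:, flip]
    return out


def sorted_window(Gk: np.ndarray) -> np.ndarray:
    """Rows reordered by ascending L1 norm (row sum), stable among ties."""
    Gk = np.asarray(Gk)
    order = np.argsort(Gk.sum(axis=1), kind="stable")
    return Gk[order]


def diversity_image(
    G_region: np.ndarray,
    window_size: int,
    stretch_size: int,
    chrom: str = "",
    position: int = 0,
    gene: str = "",
) -> DiversityImage:
    """Mean-of-sorted-windows image for a w + l - 1 SNP region.

    For each window placement k (1..w) the l-SNP submatrix is row-sorted
    by L1 norm; entry (i, j) of the image is the mean over all windows
    containing SNP j of the sorted matrices' values in SNP j's column.
    Edge SNPs are covered by fewer windows.
    """
    G = np.asarray(G_region)
    l, w = window_size, stretch_size
    width = w + l - 1
    if G.ndim != 2 or G.shape[1] != width:
        raise ValueError(f"region must have exactly w + l - 1 = {width} SNP columns")
    n = G.shape[0]
    total = np.zeros((n, width))
    count = np.zeros(width)
    for k in range(w):
        total[:, k : k + l] += sorted_window(G[:, k : k + l])
        count[k : k + l] += 1
    return DiversityImage(
        X=total / count, chrom=chrom, position=position, gene=gene
    )


def write_image_tsv(img: DiversityImage, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chrom={img.chrom} position={img.position} gene={img.gene}\n")
        for row in img.X:
            fh.write("\t".join(format(v, ".6g") for v in row) + "\n")


def render_image_png(img: DiversityImage, path: str) -> None:
    """Grayscale rendering: 0 darkest, 2 brightest (thin layer; the matrix
    TSV is the tested artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, img.X, cmap="gray", vmin=0.0, vmax=2.0)


def manhattan_table(table: PValueTable) -> pd.DataFrame:
    """Plot-ready records: chrom, position, -log10 adjusted p, significance.

    Input order is preserved within chromosomes; the significance
    threshold used downstream is carried in ``DataFrame.attrs['alpha']``.
    """
    from .calibration import DEFAULT_ALPHA

    df = pd.DataFrame(
        {
            "chrom": table.chroms,
            "position": table.anchors,
            "neglog10_p": -np.log10(table.p_adjusted),
            "significant": table.p_adjusted < DEFAULT_ALPHA,
        }
    )
    df.attrs["alpha"] = DEFAULT_ALPHA
    df.attrs["method"] = table.method
    return df


def write_manhattan_tsv(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# alpha={df.attrs.get('alpha', '')} method={df.attrs.get('method', '')}\n")
        df.to_csv(fh, sep="\t", index=False)
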