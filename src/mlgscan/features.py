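"""Feature extraction over stretches of consecutive windows.

A *stretch* is a block of w consecutive windows of summary statistics,
anchored at its center window.  Two feature sets are derived per stretch:

* **moments** — mean, variance, skewness and excess kurtosis of each of
  the m = 8 statistics across the w windows: p = 4m = 32 features.
* **fda** — each statistic's curve across the stretch is approximated by
  a least-squares expansion in B = 10 cubic B-spline basis functions
  (clamped, equally spaced interior knots on [1, w]); the curve's first
  and second derivatives ("velocity" and "acceleration") are evaluated
  analytically from the basis derivatives and re-projected onto the same
  B-dimensional basis, giving p = 3Bm = 240 features.

Feature ordering is fixed: statistic-major, then within a statistic
(mean, var, skew, kurt) for moments or (fit block, d1 block, d2 block)
for FDA, so models are reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import BSpline

from .sumstats import N_STATS, SummaryStatMatrix, distance_moments

logger = logging.getLogger(__name__)

MOMENTS = "moments"
FDA = "fda"


@dataclass
class StatStretch:
    """w consecutive rows of a summary-statistic matrix."""

    chrom: str
    S: np.ndarray  # w x m
    anchor: int  # center window's center position


@dataclass
class BasisSystem:
    """Cubic B-spline basis evaluated on the stretch grid t = 1..w.

    ``Phi`` (w x B) holds basis values; ``dPhi`` and ``d2Phi`` the analytic
    first- and second-derivative values.  ``P`` is the pseudoinverse of
    ``Phi`` used for all least-squares fits.
    """

    B: int
    order: int
    knots: np.ndarray
    t: np.ndarray
    Phi: np.ndarray
    dPhi: np.ndarray
    d2Phi: np.ndarray
    P: np.ndarray


@dataclass
class FeatureMatrix:
    """N x p feature matrix with genomic anchors.

    ``method`` is ``"moments"`` (p = 32) or ``"fda"`` (p = 240 with
    defaults).  Row i describes the stretch anchored at
    (chroms[i], anchors[i]).
    """

    method: str
    X: np.ndarray
    chroms: np.ndarray
    anchors: np.ndarray
    params: dict | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.chroms = np.asarray(self.chroms)
        self.anchors = np.asarray(self.anchors, dtype=np.int64)
        if not (len(self.X) == len(self.chroms) == len(self.anchors)):
            raise ValueError("X, chroms and anchors must have equal length")

    @property
    def n_observations(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def iter_stretches(sm: SummaryStatMatrix, stretch_size: int) -> Iterator[StatStretch]:
    """Yield all stretches of ``stretch_size`` consecutive windows.

    Count is ``n_windows - stretch_size + 1`` at stride one; the anchor is
    the center window (``stretch_size`` must be odd).  Too few windows
    yield an empty sequence with a warning.
    """
    if stretch_size < 1 or stretch_size % 2 == 0:
        raise ValueError("stretch_size must be an odd positive integer")
    nw = sm.n_windows
    if nw < stretch_size:
        logger.warning(
            "chromosome %s has %d windows < stretch size %d: no stretches",
            sm.chrom,
            nw,
            stretch_size,
        )
        return
    half = (stretch_size - 1) // 2
    for k in range(nw - stretch_size + 1):
        yield StatStretch(
            chrom=sm.chrom,
            S=sm.stats[k : k + stretch_size],
            anchor=int(sm.center_positions[k + half]),
        )


def moment_features(stretch: StatStretch) -> np.ndarray:
    """4m-vector of column-wise moments of a stretch (statistic-major)."""
    out = np.empty(4 * stretch.S.shape[1])
    for s in range(stretch.S.shape[1]):
        out[4 * s : 4 * s + 4] = distance_moments(stretch.S[:, s])
    return out


def build_basis(w: int, B: int = 10, order: int = 4) -> BasisSystem:
    """Clamped cubic B-spline basis with equally spaced knots on [1, w].

    ``order`` is the spline order (4 = cubic); there are ``B - order``
    interior knots.  Rows of ``Phi`` sum to 1 (partition of unity) and rows
    of ``dPhi`` sum to 0.
    """
    if B < order:
        raise ValueError("need at least as many basis functions as the order")
    if w <= B:
        raise ValueError("stretch length must exceed the number of basis functions")
    degree = order - 1
    interior = np.linspace(1.0, float(w), B - order + 2)[1:-1]
    knots = np.concatenate([[1.0] * order, interior, [float(w)] * order])
    t = np.arange(1, w + 1, dtype=float)
    spline = BSpline(knots, np.eye(B), degree)
    Phi = spline(t)
    dPhi = spline.derivative(1)(t)
    d2Phi = spline.derivative(2)(t)
    # guarded: full column rank is guaranteed for w >> B on this grid
    if np.linalg.matrix_rank(Phi) < B:
        raise np.linalg.LinAlgError("rank-deficient basis evaluation matrix")
    return BasisSystem(
        B=B,
        order=order,
        knots=knots,
        t=t,
        Phi=Phi,
        dPhi=dPhi,
        d2Phi=d2Phi,
        P=np.linalg.pinv(Phi),
    )


def fit_coefficients(y: np.ndarray, basis: BasisSystem) -> np.ndarray:
    """Ordinary least-squares basis coefficients minimizing ||y - Phi c||."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    return basis.P @ y


def derivative_features(
    c: np.ndarray, basis: BasisSystem, order: int
) -> np.ndarray:
    """B-vector representing the first or second derivative of a fit.

    The derivative curve Phi'c (or Phi''c) is evaluated on the stretch
    grid and re-projected onto the same B-dimensional basis by least
    squares, so each derivative contributes exactly B features.
    """
    if order == 1:
        deriv = basis.dPhi @ c
    elif order == 2:
        deriv = basis.d2Phi @ c
    else:
        raise ValueError("derivative order must be 1 or 2")
    return basis.P @ deriv


def fda_features(stretch: StatStretch, basis: BasisSystem) -> np.ndarray:
    """3Bm-vector: per statistic, the fit, velocity and acceleration blocks."""
    C = basis.P @ stretch.S  # B x m
    D1 = basis.P @ (basis.dPhi @ C)
    D2 = basis.P @ (basis.d2Phi @ C)
    m = stretch.S.shape[1]
    B = basis.B
    out = np.empty(3 * B * m)
    for s in range(m):
        base = 3 * B * s
        out[base : base + B] = C[:, s]
        out[base + B : base + 2 * B] = D1[:, s]
        out[base + 2 * B : base + 3 * B] = D2[:, s]
    return out


def _stretch_views(sm: SummaryStatMatrix, w: int) -> tuple[np.ndarray, np.ndarray]:
    """(n_stretch, w, m) sliding view plus the stretch anchors."""
    if sm.n_windows < w:
        return np.empty((0, w, sm.stats.shape[1])), np.empty(0, dtype=np.int64)
    view = sliding_window_view(sm.stats, w, axis=0)  # (n, m, w)
    half = (w - 1) // 2
    anchors = sm.center_positions[half : sm.n_windows - w + 1 + half]
    return np.swapaxes(view, 1, 2), anchors


def moment_feature_matrix(sm: SummaryStatMatrix, stretch_size: int = 129) -> FeatureMatrix:
    """Moment features for every stretch of a chromosome (vectorized)."""
    if stretch_size % 2 == 0:
        raise ValueError("stretch_size must be odd")
    S, anchors = _stretch_views(sm, stretch_size)
    n, w, m = S.shape
    mu = S.mean(axis=1)  # n x m
    dev = S - mu[:, None, :]
    m2 = np.mean(dev**2, axis=1)
    m3 = np.mean(dev**3, axis=1)
    m4 = np.mean(dev**4, axis=1)
    ok = m2 > 1e-28 * np.maximum(1.0, mu * mu)
    skew = np.zeros_like(m2)
    kurt = np.zeros_like(m2)
    skew[ok] = m3[ok] / m2[ok] ** 1.5
    kurt[ok] = m4[ok] / m2[ok] ** 2 - 3.0
    m2 = np.where(ok, m2, 0.0)
    X = np.stack([mu, m2, skew, kurt], axis=2).reshape(n, 4 * m)
    return FeatureMatrix(
        method=MOMENTS,
        X=X,
        chroms=np.full(n, sm.chrom, dtype=object),
        anchors=anchors,
        params={"w": stretch_size, "l": sm.window_size},
    )


def fda_feature_matrix(
    sm: SummaryStatMatrix, basis: BasisSystem, stretch_size: int | None = None
) -> FeatureMatrix:
    """FDA features for every stretch of a chromosome (vectorized)."""
    w = stretch_size if stretch_size is not None else len(basis.t)
    if len(basis.t) != w:
        raise ValueError("basis grid length must equal the stretch size")
    S, anchors = _stretch_views(sm, w)
    n, _, m = S.shape
    B = basis.B
    # one linear operator per block: fit, velocity, acceleration
    Pd1 = basis.P @ basis.dPhi @ basis.P
    Pd2 = basis.P @ basis.d2Phi @ basis.P
    C = np.einsum("bw,nwm->nbm", basis.P, S)
    D1 = np.einsum("bw,nwm->nbm", Pd1, S)
    D2 = np.einsum("bw,nwm->nbm", Pd2, S)
    blocks = np.stack([C, D1, D2], axis=1)  # n x 3 x B x m
    X = np.transpose(blocks, (0, 3, 1, 2)).reshape(n, 3 * B * m)
    return FeatureMatrix(
        method=FDA,
        X=X,
        chroms=np.full(n, sm.chrom, dtype=object),
        anchors=anchors,
        params={"w": w, "l": sm.window_size, "B": B},
    )


def assemble_features(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Row-concatenate per-chromosome feature matrices, keeping anchors."""
    if not parts:
        raise ValueError("no feature matrices to assemble")
    methods = {fm.method for fm in parts}
    if len(methods) != 1:
        raise ValueError(f"cannot mix feature methods: {sorted(methods)}")
    widths = {fm.n_features for fm in parts}
    if len(widths) != 1:
        raise ValueError("inconsistent feature dimension across chromosomes")
    return FeatureMatrix(
        method=parts[0].method,
        X=np.vstack([fm.X for fm in parts]),
        chroms=np.concatenate([fm.chroms for fm in parts]),
        anchors=np.concatenate([fm.anchors for fm in parts]),
        params=parts[0].params,
    )


def write_features_tsv(fm: FeatureMatrix, path: str) -> None:
    params = " ".join(f"{k}={v}" for k, v in (fm.params or {}).items())
    with open(path, "w") as fh:
        fh.write(f"# method={fm.method} {params}\n")
        cols = "\t".join(f"x{i}" for i in range(fm.n_features))
        fh.write("chrom\tanchor\t" + cols + "\n")
        for chrom, anchor, row in zip(fm.chroms, fm.anchors, fm.X):
            vals = "\t".join(format(v, ".10g") for v in row)
            fh.write(f"{chrom}\t{anchor}\t{vals}\n")


def read_features_tsv(path: str) -> FeatureMatrix:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
    meta = dict(item.split("=") for item in header.split())
    df = pd.read_csv(path, sep="\t", skiprows=1)
    xcols = [c for c in df.columns if c.startswith("x")]
    params = {k: int(v) for k, v in meta.items() if k != "method"}
    return FeatureMatrix(
        method=meta["method"],
        X=df[xcols].to_numpy(),
        chroms=df["chrom"].astype(str).to_numpy(),
        anchors=df["anchor"].to_numpy(),
        params=params,
    )
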