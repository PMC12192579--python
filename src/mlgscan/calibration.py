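"""Score-to-p-value calibration, genomic-control inflation, outlier calling.

Squared Mahalanobis distances of rows of an N x p feature matrix follow
(approximately) a Hotelling T-squared law; the transform

    F = D2 * (N - p) / (p * (N - 1))

refers them to an F(p, N - p) distribution, whose upper tail gives the
raw p-value.  Isolation-forest and one-class-SVM scores are first
shift-log transformed, then treated as a single feature (p = 1) through
the same machinery.

Raw p-values on real genomes are inflated by linkage disequilibrium.
Following the genomic-control convention, observed chi-square(1 dof)
quantiles of the p-values are regressed through the origin on expected
chi-square(1) quantiles from uniform plotting positions (i - 0.5) / N;
the slope is the inflation factor lambda, observed quantiles are divided
by it, and the deflated quantiles are converted back to p-values.
Outliers are stretches whose adjusted p-value falls below the Bonferroni
threshold alpha = 0.05 / 1e6 = 5e-8 (about one million independent loci
in the human genome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detectors import mahalanobis_squared, mahalanobis_squared_pinv
from .features import FeatureMatrix

#: Genome-wide Bonferroni significance threshold.
DEFAULT_ALPHA = 5e-8


def bonferroni_threshold(fwer: float = 0.05, n_tests: int = 1_000_000) -> float:
    """Family-wise threshold alpha = fwer / n_tests (default 0.05 / 1e6)."""
    if not 0 < fwer < 1 or n_tests < 1:
        raise ValueError("need 0 < fwer < 1 and n_tests >= 1")
    return fwer / n_tests


@dataclass
class PValueTable:
    """Per-stretch scores and calibrated p-values for one method."""

    method: str
    chroms: np.ndarray
    anchors: np.ndarray
    raw_score: np.ndarray
    d2: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    lam: float
    dof_p: int

    @property
    def n(self) -> int:
        return len(self.anchors)


@dataclass
class OutlierCallSet:
    """Significant stretches (p_adjusted < alpha), in genomic order."""

    method: str
    alpha: float
    chroms: np.ndarray
    anchors: np.ndarray
    p_adjusted: np.ndarray
    n_peaks: int
    n_total: int

    @property
    def n_outliers(self) -> int:
        return len(self.anchors)


def transform_scores(raw_score: np.ndarray) -> np.ndarray:
    """Shift-then-log transform: s' = log(s - min(s) + eps), eps = 1e-6*range.

    Normalizes and spreads detector score distributions while preserving
    order (strictly monotone increasing in s).  Scores may be negative;
    the shift guarantees positivity.
    """
    s = np.asarray(raw_score, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    rng = float(s.max() - s.min())
    if rng == 0.0:
        raise ValueError("constant score vector cannot be log-transformed")
    return np.log(s - s.min() + 1e-6 * rng)


def d2_to_pvalues(d2: np.ndarray, N: int, p: int) -> np.ndarray:
    """Upper-tail F(p, N-p) probability of the Hotelling-type statistic."""
    d2 = np.asarray(d2, dtype=float)
    if N <= p or p < 1:
        raise ValueError(f"need N > p >= 1, got N={N}, p={p}")
    f_stat = d2 * (N - p) / (p * (N - 1))
    return stats.f.sf(f_stat, p, N - p)


def estimate_lambda(p_raw: np.ndarray, method: str = "ls") -> float:
    """Inflation factor: through-origin slope of observed on expected quantiles.

    Observed chi-square(1) quantiles Q(1 - p) of the sorted p-values are
    regressed on expected quantiles at uniform plotting positions
    (i - 0.5) / N.  ``method="ls"`` (default) is the plain least-squares
    slope, which weights the extreme tail heavily; ``method="l1"``
    minimizes sum |q_obs - lambda * q_exp| (the exact minimizer is a
    weighted median of quantile ratios) and tracks the inflation of the
    null bulk, resisting a minority of genuine anomalies in the tail.
    The pipeline combines both in :func:`calibrate_pvalues`.  p-values
    of exactly 1 are clamped to 1 - 1/(2N) to keep quantiles finite;
    p-values of 0 are an error.
    """
    p = np.asarray(p_raw, dtype=float)
    N = p.size
    if N < 10:
        raise ValueError("need at least 10 p-values to estimate lambda")
    if np.any(p <= 0):
        raise ValueError("p-values of 0 cannot be converted to quantiles")
    p = np.minimum(np.sort(p), 1.0 - 1.0 / (2 * N))
    q_obs = stats.chi2.isf(p, df=1)
    q_exp = stats.chi2.isf((np.arange(1, N + 1) - 0.5) / N, df=1)
    if method == "ls":
        return float(q_exp @ q_obs / (q_exp @ q_exp))
    if method != "l1":
        raise ValueError("method must be 'l1' or 'ls'")
    ratio = q_obs / q_exp
    order = np.argsort(ratio)
    cum = np.cumsum(q_exp[order])
    return float(ratio[order][np.searchsorted(cum, 0.5 * cum[-1])])


def adjust_pvalues(p_raw: np.ndarray, lam: float) -> np.ndarray:
    """Deflate p-values by lambda on the chi-square(1) quantile scale."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    p = np.asarray(p_raw, dtype=float)
    if lam == 1.0:
        return p.copy()
    return stats.chi2.sf(stats.chi2.isf(p, df=1) / lam, df=1)


def calibrate_pvalues(
    p_raw: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    max_iter: int = 20,
) -> tuple[np.ndarray, float]:
    """Iterative genomic-control calibration robust to planted signal.

    A one-shot regression lambda is corrupted whenever genuine anomalies
    occupy a non-negligible share of the extreme tail (they drag the
    least-squares slope up, deflating the very signal the scan should
    keep).  This scheme starts from the robust bulk estimate
    (``method="l1"``), calls provisional outliers at ``alpha``, refits
    the least-squares slope on the remaining (null-like) p-values, and
    iterates until the called set stabilizes.  Following genomic-control
    convention, lambda is clamped at 1: apparent deflation (lambda < 1)
    is never used to inflate significance.  The final lambda is applied
    to all p-values.  Returns (p_adjusted, lambda).
    """
    p = np.asarray(p_raw, dtype=float)
    lam = max(1.0, estimate_lambda(p, method="l1"))
    called = np.zeros(p.size, dtype=bool)
    for _ in range(max_iter):
        p_adj = adjust_pvalues(p, lam)
        new_called = p_adj < alpha
        if np.array_equal(new_called, called) or new_called.all():
            break
        called = new_called
        lam = max(1.0, estimate_lambda(p[~called], method="ls"))
    return adjust_pvalues(p, lam), lam


def score_features(fm: FeatureMatrix, detector_scores: np.ndarray | None = None,
                   method: str | None = None,
                   alpha: float = DEFAULT_ALPHA) -> PValueTable:
    """Full calibration for one method.

    With ``detector_scores=None`` the Mahalanobis route is taken directly
    on the feature matrix.  Feature matrices carry structural
    degeneracies (the FDA derivative blocks are exact linear images of
    the fit blocks; MLG-frequency moments are constant wherever all
    sampled MLGs are distinct), so the distance is computed within the
    data's support subspace and the effective rank — not the nominal
    column count — is the dof of the F transform.  Otherwise the raw
    detector scores are shift-log transformed and referred, as a single
    feature, to F(1, N - 1) — i.e. the squared standardized score.
    """
    N = fm.n_observations
    if detector_scores is None:
        d2, dof_p = mahalanobis_squared_pinv(fm.X)
        raw = d2
    else:
        raw = np.asarray(detector_scores, dtype=float)
        if len(raw) != N:
            raise ValueError("one score per feature row required")
        d2 = mahalanobis_squared(transform_scores(raw)[:, None])
        dof_p = 1
    # extreme stretches underflow the F tail to exactly 0; floor keeps the
    # chi-square quantiles finite without moving any non-degenerate p
    p_raw = np.maximum(d2_to_pvalues(d2, N, dof_p), 1e-300)
    p_adjusted, lam = calibrate_pvalues(p_raw, alpha=alpha)
    return PValueTable(
        method=method or ("MD" if detector_scores is None else "scored"),
        chroms=fm.chroms.copy(),
        anchors=fm.anchors.copy(),
        raw_score=raw,
        d2=d2,
        p_raw=p_raw,
        p_adjusted=p_adjusted,
        lam=lam,
        dof_p=dof_p,
    )


def count_peaks(chroms: np.ndarray, significant: np.ndarray) -> int:
    """Number of maximal runs of consecutive significant windows.

    Consecutive means adjacent stretch anchors in table order within one
    chromosome; a run broken by a non-significant window or a chromosome
    boundary starts a new peak.
    """
    chroms = np.asarray(chroms)
    sig = np.asarray(significant, dtype=bool)
    peaks = 0
    prev_sig = False
    prev_chrom = None
    for c, s in zip(chroms, sig):
        if s and (not prev_sig or c != prev_chrom):
            peaks += 1
        prev_sig = s
        prev_chrom = c
    return peaks


def call_outliers(table: PValueTable, alpha: float = DEFAULT_ALPHA) -> OutlierCallSet:
    """Stretches with p_adjusted < alpha, plus the peak count."""
    sig = table.p_adjusted < alpha
    return OutlierCallSet(
        method=table.method,
        alpha=alpha,
        chroms=table.chroms[sig],
        anchors=table.anchors[sig],
        p_adjusted=table.p_adjusted[sig],
        n_peaks=count_peaks(table.chroms, sig),
        n_total=table.n,
    )


def write_pvalue_tsv(table: PValueTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# method={table.method} lambda={table.lam:.10g} dof_p={table.dof_p}\n"
        )
        fh.write("chrom\tanchor\traw_score\td2\tp_raw\tp_adjusted\n")
        for row in zip(
            table.chroms, table.anchors, table.raw_score, table.d2,
            table.p_raw, table.p_adjusted,
        ):
            c, a, r, d, pr, pa = row
            fh.write(f"{c}\t{a}\t{r:.10g}\t{d:.10g}\t{pr:.6e}\t{pa:.6e}\n")
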