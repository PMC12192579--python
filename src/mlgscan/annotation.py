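"""Annotation intersection and enrichment statistics for outlier regions.

Outlier stretches are labeled by their anchor position against BED
annotation intervals (genes/exons/introns/UTRs, repeats) and score tracks
(GC fraction, CRG alignability/mappability).  Enrichment relative to the
background of all scored stretches is assessed with a multinomial
uniformity test and two-tailed binomial tests, both calibrated by label
permutation to absorb the correlation among adjacent windows induced by
linkage disequilibrium.

Coordinates are BED half-open 0-based throughout.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Sub-label precedence when genic intervals overlap.
GENIC_PRECEDENCE = ("5'UTR", "3'UTR", "exon", "intron")

#: CRG alignability/mappability at or below this marks low confidence.
CRG_LOW_CONFIDENCE = 0.9


def read_bed(path: str, score: bool = False) -> pd.DataFrame:
    """Read BED 4/5: chrom, start, end, name[, score]."""
    names = ["chrom", "start", "end", "name"] + (["score"] if score else [])
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=range(len(names)),
        names=names,
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: BED intervals require start < end")
    return df


@dataclass
class AnnotationSet:
    """Gene models, repeat intervals and score tracks for labeling anchors.

    ``transcripts`` needs columns chrom/start/end/name where ``name`` is
    the gene symbol (one row per transcript); only the longest transcript
    per gene is used.  ``genic_features`` holds exon/intron/UTR intervals
    with the label in ``name``.  Score tracks map value columns over
    intervals.
    """

    transcripts: pd.DataFrame | None = None
    genic_features: pd.DataFrame | None = None
    repeats: pd.DataFrame | None = None
    gc_track: pd.DataFrame | None = None
    crg_track: pd.DataFrame | None = None

    def genes(self) -> pd.DataFrame:
        if self.transcripts is None or self.transcripts.empty:
            return pd.DataFrame(columns=["chrom", "start", "end", "name"])
        return longest_transcripts(self.transcripts)


def longest_transcripts(transcripts: pd.DataFrame) -> pd.DataFrame:
    """One interval per gene: maximal end - start, ties to first in file."""
    df = transcripts.reset_index(drop=True).copy()
    df["_span"] = df["end"] - df["start"]
    idx = (
        df.sort_values(["_span"], ascending=False, kind="stable")
        .drop_duplicates("name")
        .index
    )
    return df.loc[sorted(idx), ["chrom", "start", "end", "name"]].reset_index(
        drop=True
    )


def _contains(intervals: pd.DataFrame, chrom: str, pos: int) -> pd.DataFrame:
    sub = intervals[intervals["chrom"] == chrom]
    return sub[(sub["start"] <= pos) & (pos < sub["end"])]


def intersect_annotations(
    chroms: np.ndarray, positions: np.ndarray, annotations: AnnotationSet
) -> pd.DataFrame:
    """Label each anchor genic/intergenic with a genic sub-label.

    An anchor is genic if it falls inside the longest transcript of any
    gene (half-open interval).  Genic anchors get a sub-label from the
    genic feature intervals with precedence 5'UTR/3'UTR > exon > intron;
    a genic anchor hitting no feature interval defaults to intron.
    """
    genes = annotations.genes()
    feats = annotations.genic_features
    records = []
    for chrom, pos in zip(chroms, positions):
        hit = _contains(genes, str(chrom), int(pos))
        if hit.empty:
            records.append(("intergenic", "", ""))
            continue
        gene_names = ",".join(hit["name"].astype(str))
        sub = "intron"
        if feats is not None and not feats.empty:
            labels = set(_contains(feats, str(chrom), int(pos))["name"])
            for cand in GENIC_PRECEDENCE:
                if cand in labels:
                    sub = cand
                    break
        records.append(("genic", sub, gene_names))
    return pd.DataFrame(
        {
            "chrom": chroms,
            "position": positions,
            "label": [r[0] for r in records],
            "sublabel": [r[1] for r in records],
            "genes": [r[2] for r in records],
        }
    )


def track_values(
    chroms: np.ndarray, positions: np.ndarray, track: pd.DataFrame
) -> np.ndarray:
    """Score-track value at each anchor; NaN where the track has no cover."""
    out = np.full(len(positions), np.nan)
    for i, (chrom, pos) in enumerate(zip(chroms, positions)):
        hit = _contains(track, str(chrom), int(pos))
        if not hit.empty:
            out[i] = float(hit["score"].iloc[0])
    n_uncovered = int(np.isnan(out).sum())
    if n_uncovered:
        logger.warning("%d anchor(s) not covered by score track", n_uncovered)
    return out


def classify_low_confidence(
    chroms: np.ndarray, positions: np.ndarray, crg_track: pd.DataFrame
) -> np.ndarray:
    """True where the CRG score at the anchor is <= 0.9 (inclusive).

    Anchors without track cover come back NaN-masked (excluded): the
    returned array is float with NaN for uncovered, 1.0 low-confidence,
    0.0 otherwise.
    """
    vals = track_values(chroms, positions, crg_track)
    out = np.where(np.isnan(vals), np.nan, (vals <= CRG_LOW_CONFIDENCE).astype(float))
    return out


@dataclass
class EnrichmentResult:
    """One enrichment test: observed count vs expected proportion."""

    label: str
    observed: int
    total: int
    expected_prop: float
    pvalue: float
    perm_pvalue: float | None
    alpha: float
    test: str


def multinomial_uniformity_test(
    observed: np.ndarray,
    expected_props: np.ndarray,
    exact_limit: int = 500,
    max_outcomes: int = 500_000,
) -> tuple[float, str]:
    """Goodness-of-fit p-value for counts against expected proportions.

    For small totals an exact multinomial test is run: the p-value sums
    the probabilities of all outcomes no more likely than the observed
    one.  Beyond ``exact_limit`` total counts (or when the outcome space
    exceeds ``max_outcomes``) a chi-square approximation is used.
    Returns (p-value, "exact" or "chi2").
    """
    obs = np.asarray(observed, dtype=int)
    props = np.asarray(expected_props, dtype=float)
    if obs.ndim != 1 or obs.shape != props.shape:
        raise ValueError("observed and expected_props must be equal-length vectors")
    if np.any(obs < 0) or np.any(props < 0):
        raise ValueError("counts and proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    n = int(obs.sum())
    if n == 0:
        raise ValueError("zero total count")
    k = len(obs)
    n_outcomes = _n_compositions(n, k)
    if n <= exact_limit and n_outcomes <= max_outcomes:
        p_obs = stats.multinomial.pmf(obs, n, props)
        outcomes = np.array(list(_compositions(n, k)), dtype=int)
        pmf = stats.multinomial.pmf(outcomes, n, props)
        total = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
        return min(total, 1.0), "exact"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.chisquare(obs, f_exp=n * props)
    return float(p), "chi2"


def _n_compositions(n: int, k: int) -> int:
    from math import comb

    return comb(n + k - 1, k - 1)


def _compositions(n: int, k: int):
    """All length-k non-negative integer vectors summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)


def binomial_enrichment_test(x: int, n: int, p: float) -> float:
    """Exact two-tailed binomial p-value, minimum-likelihood method.

    Sums the probabilities of all outcome counts whose probability does
    not exceed that of the observed x (scipy's two-sided convention).
    """
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("need 0 <= p <= 1")
    return float(stats.binomtest(x, n, p, alternative="two-sided").pvalue)


def permutation_pvalue(
    test_fn,
    labels: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> float:
    """Fraction of permuted-label test p-values strictly below the observed.

    ``test_fn`` maps a label vector to a p-value; labels are shuffled
    ``n_perm`` times with a seeded generator.  Absorbs the dependence
    among adjacent windows that the analytic tests ignore.
    """
    labels = np.asarray(labels)
    observed = test_fn(labels)
    rng = np.random.default_rng(seed)
    smaller = 0
    for _ in range(n_perm):
        if test_fn(rng.permutation(labels)) < observed:
            smaller += 1
    return smaller / n_perm


def rank_genes(
    outlier_chroms: np.ndarray,
    outlier_anchors: np.ndarray,
    outlier_pvalues: np.ndarray,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Rank genes by the minimum adjusted p-value of overlapping outliers.

    A gene scores the minimum p over outlier anchors inside its interval;
    genes with no overlapping outlier are absent.  Output is sorted
    ascending by p, ties broken by genomic order — suitable as a ranked
    single-list input to GO enrichment tools.
    """
    rows = []
    for _, gene in genes.iterrows():
        mask = (
            (np.asarray(outlier_chroms).astype(str) == str(gene["chrom"]))
            & (outlier_anchors >= gene["start"])
            & (outlier_anchors < gene["end"])
        )
        if mask.any():
            rows.append(
                (gene["name"], gene["chrom"], gene["start"],
                 float(np.min(outlier_pvalues[mask])))
            )
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "min_p"])
    return (
        df.sort_values(["min_p", "chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )


def enrichment_by_category(
    categories: np.ndarray,
    is_outlier: np.ndarray,
    alpha: float,
    n_perm: int = 10_000,
    seed: int | None = 0,
    category_order: list | None = None,
) -> tuple[float, str, float, list[EnrichmentResult]]:
    """Full family of tests for one categorical labeling of anchors.

    Runs the multinomial uniformity test of outlier counts against the
    background category proportions, then one two-tailed binomial test
    per category, each with a permutation p-value obtained by shuffling
    the category labels across anchors (outlier status fixed).

    Returns (multinomial p, multinomial test kind, multinomial
    permutation p, per-category binomial results).
    """
    categories = np.asarray(categories)
    is_outlier = np.asarray(is_outlier, dtype=bool)
    if category_order is None:
        category_order = sorted(pd.unique(categories))
    n_total = int(is_outlier.sum())
    if n_total == 0:
        raise ValueError("no outliers to characterize")

    def counts(labels: np.ndarray) -> np.ndarray:
        lab = pd.Categorical(labels[is_outlier], categories=category_order)
        return np.asarray(lab.value_counts().reindex(category_order), dtype=int)

    bg = pd.Categorical(categories, categories=category_order).value_counts()
    props = np.asarray(bg.reindex(category_order), dtype=float)
    props = props / props.sum()

    def multi_fn(labels: np.ndarray) -> float:
        return multinomial_uniformity_test(counts(labels), props)[0]

    multi_p, multi_kind = multinomial_uniformity_test(counts(categories), props)
    multi_perm = permutation_pvalue(multi_fn, categories, n_perm=n_perm, seed=seed)

    results = []
    obs = counts(categories)
    for j, cat in enumerate(category_order):
        x, prop = int(obs[j]), float(props[j])

        def binom_fn(labels: np.ndarray, _j=j) -> float:
            return binomial_enrichment_test(int(counts(labels)[_j]), n_total, props[_j])

        perm = permutation_pvalue(
            binom_fn, categories, n_perm=n_perm,
            seed=None if seed is None else seed + 1 + j,
        )
        results.append(
            EnrichmentResult(
                label=str(cat),
                observed=x,
                total=n_total,
                expected_prop=prop,
                pvalue=binomial_enrichment_test(x, n_total, prop),
                perm_pvalue=perm,
                alpha=alpha,
                test="binomial",
            )
        )
    return multi_p, multi_kind, multi_perm, results
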