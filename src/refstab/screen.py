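"""Transcriptome-wide screening for candidate reference genes.

Raw count matrices are normalized with median-of-ratios size factors, each
gene is summarised by its mean normalized count and coefficient of variation
(CV = sample SD / mean on the linear count scale), and candidates are the
lowest-CV genes above an expression floor. Matrices from two genome
annotations can be joined through a strict 1:1 ortholog map first.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EstimationError, ValidationError
from .io import CountMatrix

logger = logging.getLogger(__name__)


def _as_count_matrix(X) -> CountMatrix:
    if isinstance(X, CountMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return CountMatrix(X)
    raise TypeError(f"expected CountMatrix or DataFrame, got {type(X).__name__}")


def median_of_ratios_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample size factors by the median-of-ratios procedure.

    For each sample j, s_j = median over reference genes i of
    value(i, j) / geomean_over_samples(value(i, .)), where the reference set
    is every gene with no zero count in any sample (strict zero-exclusion,
    no pseudocounts).
    """
    cm = _as_count_matrix(counts).validate()
    vals = cm.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise EstimationError("size-factor estimation needs at least 2 samples")
    ref = (vals > 0).all(axis=1)
    if not ref.any():
        raise EstimationError(
            "no gene has nonzero counts in every sample; cannot form the "
            "geometric-mean reference (pseudo-reference fallback is disabled)"
        )
    logref = np.log(vals[ref])
    geomean = np.exp(logref.mean(axis=1))
    ratios = vals[ref] / geomean[:, None]
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=cm.values.columns, name="size_factor")


def normalize_counts(
    counts: CountMatrix | pd.DataFrame, size_factors: pd.Series | Sequence[float]
) -> CountMatrix:
    """Divide each sample column by its size factor."""
    cm = _as_count_matrix(counts)
    sf = np.asarray(size_factors, dtype=float)
    if len(sf) != cm.values.shape[1]:
        raise ValidationError(
            f"{len(sf)} size factors for {cm.values.shape[1]} samples"
        )
    if not (np.isfinite(sf).all() and (sf > 0).all()):
        raise ValidationError("size factors must be positive and finite")
    norm = cm.values / sf
    return CountMatrix(
        norm,
        size_factors=pd.Series(sf, index=cm.values.columns, name="size_factor"),
        sample_meta=cm.sample_meta,
    )


def gene_stats(norm: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Mean normalized count and CV per gene (linear scale, n-1 SD).

    Genes with mean 0 get CV = NaN and ``cv_undefined`` = True.
    """
    cm = _as_count_matrix(norm)
    vals = cm.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise EstimationError("CV needs at least 2 samples (SD undefined)")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {"mean_expr": mean, "cv": cv, "cv_undefined": mean <= 0},
        index=cm.values.index,
    )


def screen_candidates(
    stats: pd.DataFrame, min_mean: float = 100.0, top_k: int = 25
) -> pd.DataFrame:
    """Rank genes above the expression floor by ascending CV; return top_k.

    Ranks are fractional (average on CV ties) and contiguous over the genes
    passing the floor; output row order is CV ascending then gene label.
    """
    passing = stats[(stats["mean_expr"] >= min_mean) & ~stats["cv_undefined"]].copy()
    if passing.empty:
        warnings.warn(
            f"no gene passes the expression floor of {min_mean}", stacklevel=2
        )
        return passing.assign(rank=pd.Series(dtype=float))
    passing["rank"] = passing["cv"].rank(method="average")
    # deterministic output order: cv ascending, ties by gene label
    passing = passing.iloc[
        np.lexsort((passing.index.astype(str), passing["cv"].to_numpy()))
    ]
    return passing.head(top_k)


def clean_ortholog_map(pairs: pd.DataFrame) -> pd.DataFrame:
    """Reduce an ortholog pair list to strict 1:1 by removing *every* pair
    involving a gene that occurs more than once on either side."""
    a, b = pairs.columns[:2]
    dup_a = pairs[a].duplicated(keep=False)
    dup_b = pairs[b].duplicated(keep=False)
    removed = int((dup_a | dup_b).sum())
    if removed:
        logger.info("removed %d many-to-many ortholog pair(s)", removed)
    return pairs[~(dup_a | dup_b)].reset_index(drop=True)


def join_orthologs(
    a: CountMatrix | pd.DataFrame,
    b: CountMatrix | pd.DataFrame,
    pairs: pd.DataFrame,
) -> CountMatrix:
    """Join two annotations' matrices on a cleaned 1:1 ortholog map.

    Rows are restricted to mapped pairs present in both matrices, relabeled
    to the A-side identifier; columns are A's samples followed by B's.
    """
    cma, cmb = _as_count_matrix(a), _as_count_matrix(b)
    pairs = clean_ortholog_map(pairs)
    ca, cb = pairs.columns[:2]
    present = pairs[pairs[ca].isin(cma.values.index) & pairs[cb].isin(cmb.values.index)]
    dropped = len(pairs) - len(present)
    if dropped:
        logger.info("dropped %d ortholog pair(s) absent from a matrix", dropped)
    if present.empty:
        raise ValidationError("ortholog join produced an empty gene set")
    left = cma.values.loc[present[ca]]
    right = cmb.values.loc[present[cb]]
    right.index = left.index
    joined = pd.concat([left, right], axis=1)
    meta = None
    if cma.sample_meta is not None and cmb.sample_meta is not None:
        meta = pd.concat([cma.sample_meta, cmb.sample_meta])
    return CountMatrix(joined, sample_meta=meta)


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios count normalization as an sklearn transformer.

    ``fit`` estimates per-sample size factors from the gene x sample matrix;
    ``transform`` divides each sample by its factor.

    Attributes
    ----------
    size_factors_ : pd.Series
        Estimated per-sample size factors.
    """

    def fit(self, X, y=None):
        self.size_factors_ = median_of_ratios_size_factors(X)
        return self

    def transform(self, X) -> CountMatrix:
        cm = _as_count_matrix(X)
        if list(cm.values.columns) != list(self.size_factors_.index):
            raise ValidationError("samples differ from those seen at fit time")
        return normalize_counts(cm, self.size_factors_)


class CVScreen(BaseEstimator):
    """Coefficient-of-variation screen for candidate reference genes.

    Fitting normalizes the matrix (unless ``already_normalized``), computes
    per-gene mean expression and CV, and ranks genes with
    mean >= ``min_mean`` by ascending CV.

    Parameters
    ----------
    min_mean : float
        Expression floor on the mean normalized count.
    top_k : int
        Number of candidates to retain.
    already_normalized : bool
        Skip size-factor estimation for pre-normalized matrices.

    Attributes
    ----------
    size_factors_ : pd.Series or None
    stats_ : pd.DataFrame        mean_expr / cv / cv_undefined per gene
    candidates_ : pd.DataFrame   the ranked top_k screen result
    """

    def __init__(self, min_mean: float = 100.0, top_k: int = 25,
                 already_normalized: bool = False):
        self.min_mean = min_mean
        self.top_k = top_k
        self.already_normalized = already_normalized

    def fit(self, X, y=None):
        cm = _as_count_matrix(X).validate()
        if self.already_normalized:
            self.size_factors_ = None
            norm = cm
        else:
            self.size_factors_ = median_of_ratios_size_factors(cm)
            norm = normalize_counts(cm, self.size_factors_)
        self.stats_ = gene_stats(norm)
        self.candidates_ = screen_candidates(
            self.stats_, min_mean=self.min_mean, top_k=self.top_k
        )
        return self
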