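"""Expression-stability scoring of candidate reference genes.

Four classical algorithms are implemented on an aggregated gene x sample Ct
matrix and combined into a consensus:

* geNorm — a gene's M value is its mean pairwise variation, the SD over
  samples of the log2 ratio of its relative quantity to each other gene's;
  genes are eliminated stepwise from the highest M until two remain.
* NormFinder — a model-based variance decomposition of log2 quantities;
  without groups, the stability value is the estimated gene-wise residual
  SD under the two-way additive (gene + sample) model with heterogeneous
  variances; with groups, intergroup bias (shrunken) and intragroup
  variance are combined.
* BestKeeper — descriptive: per-gene SD and CV% of raw Ct and the Pearson
  correlation with the per-sample geometric-mean index; the ranking key is
  the SD.
* Comparative delta-Ct — a gene's stability is the mean, over all other
  genes, of the SD of their per-sample Ct difference.

The consensus is the geometric mean of the four per-method ranks
(fractional on ties), mirroring the widely used comprehensive-ranking
convention; geNorm contributes its stepwise-exclusion ranking, with the
final surviving pair sharing rank 1.5.

All SDs use the n-1 denominator. With the default efficiency E = 2 the
log2-quantity transformation reduces to arithmetic on Ct directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import EstimationError, ValidationError
from .io import (
    CtTable,
    EfficiencyMap,
    StabilityReport,
    StabilityScores,
    aggregate_technical_reps,
)


def _as_efficiency_map(eff) -> EfficiencyMap:
    if eff is None:
        return EfficiencyMap()
    if isinstance(eff, EfficiencyMap):
        return eff
    return EfficiencyMap(dict(eff))


def relative_quantities(
    ct: pd.DataFrame, efficiencies: EfficiencyMap | dict | None = None
) -> pd.DataFrame:
    """Efficiency-corrected relative quantities Q(g, s) = E_g^(minCt_g - Ct(g, s)).

    Each gene's best (lowest-Ct) sample gets Q = 1; all others fall in (0, 1].
    """
    eff = _as_efficiency_map(efficiencies)
    if ct.isna().any().any():
        raise ValidationError("Ct matrix must be complete (no NaN)")
    e = np.array([eff.get_efficiency(g) for g in ct.index])
    delta = ct.min(axis=1).to_numpy()[:, None] - ct.to_numpy(dtype=float)
    return pd.DataFrame(e[:, None] ** delta, index=ct.index, columns=ct.columns)


def log2_quantities(
    ct: pd.DataFrame, efficiencies: EfficiencyMap | dict | None = None
) -> pd.DataFrame:
    """log2 of :func:`relative_quantities`; with E = 2 this is minCt - Ct."""
    eff = _as_efficiency_map(efficiencies)
    e = np.array([eff.get_efficiency(g) for g in ct.index])
    delta = ct.min(axis=1).to_numpy()[:, None] - ct.to_numpy(dtype=float)
    return pd.DataFrame(
        delta * np.log2(e)[:, None], index=ct.index, columns=ct.columns
    )


# ---------------------------------------------------------------------------
# geNorm


@dataclass
class GenormResult:
    m_values: pd.Series            # initial M for every gene
    exclusion_order: list[str]     # first removed = least stable
    ranking: pd.Series             # stepwise ranking; final pair at 1.5

    @property
    def final_pair(self) -> tuple[str, str]:
        pair = self.ranking.index[self.ranking == 1.5]
        return tuple(sorted(pair))


def _genorm_m(logq: np.ndarray) -> np.ndarray:
    """Mean pairwise log-ratio SD for each row of a log2-quantity matrix."""
    g = logq.shape[0]
    m = np.zeros(g)
    for j in range(g):
        sds = [np.std(logq[j] - logq[k], ddof=1) for k in range(g) if k != j]
        m[j] = float(np.mean(sds))
    return m


def genorm(q: pd.DataFrame) -> GenormResult:
    """geNorm stability analysis of a gene x sample quantity matrix.

    Returns the initial M values, the stepwise exclusion order and the
    resulting ranking (1 = most stable); the final surviving pair cannot be
    separated and shares the average rank 1.5. M ties during elimination are
    broken by removing the lexicographically last gene label.
    """
    genes = list(q.index)
    if len(genes) < 3:
        raise EstimationError("geNorm needs at least 3 genes")
    if q.shape[1] < 2:
        raise EstimationError("geNorm needs at least 2 samples")
    logq = np.log2(q.to_numpy(dtype=float))
    m_init = pd.Series(_genorm_m(logq), index=genes, name="genorm_m")

    remaining = list(genes)
    sub = logq.copy()
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = _genorm_m(sub)
        worst = max(range(len(remaining)), key=lambda i: (m[i], remaining[i]))
        exclusion.append(remaining[worst])
        remaining = remaining[:worst] + remaining[worst + 1:]
        sub = np.delete(sub, worst, axis=0)
    ranking = pd.Series(index=pd.Index(genes, name="gene"), dtype=float, name="genorm_rank")
    for i, gid in enumerate(exclusion):  # first removed = worst rank
        ranking[gid] = len(genes) - i
    for gid in remaining:
        ranking[gid] = 1.5
    return GenormResult(m_values=m_init, exclusion_order=exclusion, ranking=ranking)


def genorm_pairwise_variation(q: pd.DataFrame, ranking: pd.Series) -> pd.Series:
    """geNorm's V(n, n+1) series for n = 2 .. G-1.

    NF_n is the per-sample geometric mean of the n top-ranked genes'
    quantities; V(n, n+1) is the SD over samples of log2(NF_n / NF_{n+1}).
    Guides how many reference genes a normalization factor should use.
    """
    genes_by_rank = list(ranking.sort_values(kind="mergesort").index)
    g = len(genes_by_rank)
    if g < 3:
        raise EstimationError("pairwise variation needs at least 3 genes")
    logq = np.log2(q.loc[genes_by_rank].to_numpy(dtype=float))
    v = {}
    for n in range(2, g):
        nf_n = logq[:n].mean(axis=0)          # log2 of geometric mean
        nf_n1 = logq[: n + 1].mean(axis=0)
        v[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return pd.Series(v, name="pairwise_variation")


# ---------------------------------------------------------------------------
# NormFinder


def _unbiased_gene_variances(y: np.ndarray) -> np.ndarray:
    """Gene-wise residual variances under the additive gene + sample model.

    Residuals r = y - rowmean - colmean + grandmean satisfy
    E[sum_s r^2 / (S-1)] = sigma_g^2 (1 - 2/G) + T / G^2 with T = sum sigma^2,
    giving the unbiased estimator
    sigma_g^2 = G/(G-2) * (d_g - sum_h d_h / (G (G-1))), clipped at 0.
    """
    g, s = y.shape
    r = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    d = (r**2).sum(axis=1) / (s - 1)
    return np.clip(g / (g - 2) * (d - d.sum() / (g * (g - 1))), 0.0, None)


def normfinder(
    ct: pd.DataFrame,
    groups: pd.Series | dict | None = None,
    efficiencies: EfficiencyMap | dict | None = None,
) -> pd.Series:
    """NormFinder stability values (rho) on log2 quantities.

    Without groups, rho is the estimated gene-wise residual SD of the
    two-way additive model. With per-sample group labels, each gene's
    shrunken absolute intergroup difference and its intragroup variance are
    combined: rho_g = mean_k( |d~_gk| + sqrt(sigma^2_gk / n_k) ).

    Needs >= 3 genes and >= 2 samples; a grouping with fewer than 2 groups
    of >= 2 samples each falls back to the ungrouped analysis with a warning.
    """
    if ct.shape[0] < 3:
        raise EstimationError("NormFinder needs at least 3 genes")
    if ct.shape[1] < 2:
        raise EstimationError("NormFinder needs at least 2 samples")
    y = log2_quantities(ct, efficiencies).to_numpy(dtype=float)
    genes = ct.index

    if groups is not None:
        gl = pd.Series(groups).reindex(ct.columns)
        if gl.isna().any():
            raise ValidationError("every sample needs a group label")
        counts = gl.value_counts()
        if len(counts) < 2 or (counts < 2).any():
            warnings.warn(
                "need >= 2 groups with >= 2 samples each; "
                "falling back to ungrouped NormFinder",
                stacklevel=2,
            )
            groups = None
        else:
            return pd.Series(
                _normfinder_grouped(y, gl.to_numpy()), index=genes, name="normfinder_rho"
            )
    rho = np.sqrt(_unbiased_gene_variances(y))
    return pd.Series(rho, index=genes, name="normfinder_rho")


def _normfinder_grouped(y: np.ndarray, labels: np.ndarray) -> np.ndarray:
    g = y.shape[0]
    group_ids = list(dict.fromkeys(labels))
    k = len(group_ids)
    n = np.array([(labels == gid).sum() for gid in group_ids])
    # per-group intragroup variances
    sigma2 = np.empty((g, k))
    means = np.empty((g, k))
    for j, gid in enumerate(group_ids):
        block = y[:, labels == gid]
        sigma2[:, j] = _unbiased_gene_variances(block)
        means[:, j] = block.mean(axis=1)
    # intergroup differences: double-centered gene x group means
    d = means - means.mean(axis=1, keepdims=True) - means.mean(axis=0, keepdims=True) \
        + means.mean()
    # empirical-Bayes shrinkage of d toward 0
    gamma2 = (d**2).sum() / ((g - 1) * (k - 1)) - (sigma2 / n).mean()
    gamma2 = max(gamma2, 0.0)
    var_term = sigma2 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(gamma2 + var_term > 0, gamma2 / (gamma2 + var_term), 0.0)
    d_tilde = d * shrink
    return (np.abs(d_tilde) + np.sqrt(var_term)).mean(axis=1)


# ---------------------------------------------------------------------------
# BestKeeper


def bestkeeper(ct: pd.DataFrame) -> pd.DataFrame:
    """BestKeeper descriptors per gene: SD of Ct, CV% and correlation with
    the per-sample geometric-mean index.

    Genes with SD > 1.0 cycle are flagged inconsistent; a zero-variance gene
    keeps sd = 0 but gets r = NaN (undefined correlation). Ranking key for
    the consensus is the SD, ascending.
    """
    if ct.shape[1] < 2:
        raise EstimationError("BestKeeper needs at least 2 samples")
    vals = ct.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValidationError("BestKeeper requires positive Ct values")
    sd = vals.std(axis=1, ddof=1)
    mean = vals.mean(axis=1)
    cv = 100.0 * sd / mean
    index = np.exp(np.log(vals).mean(axis=0))  # per-sample geometric mean
    r = np.full(len(ct), np.nan)
    idx_sd = index.std()
    for i in range(len(ct)):
        if sd[i] > 0 and idx_sd > 0:
            r[i] = float(np.corrcoef(vals[i], index)[0, 1])
    return pd.DataFrame(
        {
            "bestkeeper_sd": sd,
            "bestkeeper_cv_pct": cv,
            "bestkeeper_r": r,
            "inconsistent": sd > 1.0,
        },
        index=ct.index,
    )


def bestkeeper_index(ct: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of Ct across all candidate genes."""
    vals = ct.to_numpy(dtype=float)
    return pd.Series(np.exp(np.log(vals).mean(axis=0)), index=ct.columns, name="bk_index")


# ---------------------------------------------------------------------------
# comparative delta-Ct


def delta_ct_stability(ct: pd.DataFrame) -> pd.Series:
    """Mean pairwise SD: for each gene g, the average over all other genes k
    of the SD (over samples) of Ct_g - Ct_k."""
    if ct.shape[0] < 2:
        raise EstimationError("the comparative delta-Ct method needs >= 2 genes")
    if ct.shape[1] < 2:
        raise EstimationError("the comparative delta-Ct method needs >= 2 samples")
    vals = ct.to_numpy(dtype=float)
    g = vals.shape[0]
    out = np.zeros(g)
    for j in range(g):
        sds = [np.std(vals[j] - vals[k], ddof=1) for k in range(g) if k != j]
        out[j] = float(np.mean(sds))
    return pd.Series(out, index=ct.index, name="deltact_sd")


# ---------------------------------------------------------------------------
# consensus


def composite_rank(ranks: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean consensus of per-method rank vectors.

    ``ranks`` holds one column per method (1 = most stable). Returns a frame
    with ``composite_geomean`` — the geometric mean across methods — and
    ``final_rank``, the fractional ranking of the composite.
    """
    if ranks.isna().any().any():
        raise ValidationError("rank matrix must be complete across methods")
    geo = np.exp(np.log(ranks.to_numpy(dtype=float)).mean(axis=1))
    out = pd.DataFrame({"composite_geomean": geo}, index=ranks.index)
    out["final_rank"] = out["composite_geomean"].rank(method="average")
    return out


def fractional_ranks(scores: pd.Series) -> pd.Series:
    """Ascending fractional (average-on-ties) ranks; 1 = most stable."""
    return scores.rank(method="average")


def stability_scores(
    ct: pd.DataFrame,
    efficiencies: EfficiencyMap | dict | None = None,
    groups: pd.Series | dict | None = None,
) -> StabilityScores:
    """Run all four methods plus the consensus on an aggregated Ct matrix."""
    q = relative_quantities(ct, efficiencies)
    gn = genorm(q)
    nf = normfinder(ct, groups=groups, efficiencies=efficiencies)
    bk = bestkeeper(ct)
    dc = delta_ct_stability(ct)
    ranks = pd.DataFrame(
        {
            "genorm": gn.ranking,
            "normfinder": fractional_ranks(nf),
            "bestkeeper": fractional_ranks(bk["bestkeeper_sd"]),
            "deltact": fractional_ranks(dc),
        }
    )
    comp = composite_rank(ranks)
    table = pd.DataFrame(
        {
            "genorm_m": gn.m_values,
            "genorm_rank": ranks["genorm"],
            "normfinder_rho": nf,
            "normfinder_rank": ranks["normfinder"],
            "bestkeeper_sd": bk["bestkeeper_sd"],
            "bestkeeper_cv_pct": bk["bestkeeper_cv_pct"],
            "bestkeeper_r": bk["bestkeeper_r"],
            "bestkeeper_rank": ranks["bestkeeper"],
            "deltact_sd": dc,
            "deltact_rank": ranks["deltact"],
            "composite_geomean": comp["composite_geomean"],
            "final_rank": comp["final_rank"],
        }
    )
    table.index.name = "gene"
    return StabilityScores(table)


def derive_stage_labels(table: CtTable) -> pd.Series:
    """Map each sample's timepoint to 'early'/'late' per (strain, condition).

    The first harvest of each condition (numeric-aware ordering of the
    timepoint labels) is 'early'; every later one is 'late'.
    """
    def _key(tp: str):
        digits = "".join(ch for ch in str(tp) if ch.isdigit() or ch == ".")
        try:
            return (0, float(digits))
        except ValueError:
            return (1, str(tp))

    meta = table.sample_meta()
    stage = {}
    for (_, _), sub in meta.groupby(["strain", "condition"], sort=False):
        tps = sorted(sub["timepoint"].unique(), key=_key)
        first = tps[0]
        for sid, tp in sub["timepoint"].items():
            stage[sid] = "early" if tp == first else "late"
    return pd.Series(stage, name="stage").loc[meta.index]


def subset_stability(
    table: CtTable,
    efficiencies: EfficiencyMap | dict | None = None,
    partition: str = "strain",
    groups_key: str | None = None,
    spread_limit: float = 1.0,
) -> StabilityReport:
    """Full four-method + consensus analysis on all samples and independently
    within each level of ``partition`` ('strain', 'timepoint', 'condition'
    or 'stage', the derived early/late label).

    Subsets violating a method's preconditions are skipped with a warning;
    the remaining subsets and the combined analysis are still reported.
    """
    agg = aggregate_technical_reps(table, spread_limit=spread_limit)
    meta = agg.sample_meta()
    if partition == "stage":
        part_labels = derive_stage_labels(agg)
    elif partition in meta.columns:
        part_labels = meta[partition]
    else:
        raise ValidationError(f"unknown partition key {partition!r}")

    def _scores_for(sample_ids) -> StabilityScores:
        sub = CtTable(agg.data[agg.data["sample"].isin(sample_ids)].copy())
        ct = sub.to_wide()
        grp = None
        if groups_key is not None:
            grp = sub.sample_meta()[groups_key]
        return stability_scores(ct, efficiencies=efficiencies, groups=grp)

    report = StabilityReport(scores=_scores_for(meta.index))
    for level in dict.fromkeys(part_labels):
        ids = part_labels.index[part_labels == level]
        try:
            report.subset_scores[f"{partition}={level}"] = _scores_for(ids)
        except (EstimationError, ValidationError) as exc:
            warnings.warn(f"skipping subset {partition}={level}: {exc}", stacklevel=2)
    return report


class StabilityRanker(BaseEstimator):
    """Consensus reference-gene stability ranking as an sklearn estimator.

    ``fit`` accepts either a replicate-resolved :class:`~refstab.io.CtTable`
    (technical replicates are averaged first) or an aggregated gene x sample
    Ct DataFrame, and runs geNorm, NormFinder, BestKeeper and the
    comparative delta-Ct method plus their geometric-mean consensus.

    Parameters
    ----------
    efficiencies : mapping gene -> E, optional
        Amplification efficiencies; absent genes default to E = 2.
    group_by : str, optional
        Metadata column ('strain', 'condition', 'timepoint') used as
        NormFinder's grouping variable (CtTable input only).
    subset_by : str, optional
        Additionally analyse each level of this metadata column
        independently (results in ``subset_scores_``).
    spread_limit : float
        Technical-replicate spread (cycles) above which wells are flagged.

    Attributes
    ----------
    scores_ : StabilityScores
    ranking_ : pd.Series          consensus final rank per gene
    genorm_ : GenormResult
    pairwise_variation_ : pd.Series
    subset_scores_ : dict[str, StabilityScores]
    """

    def __init__(self, efficiencies=None, group_by: str | None = None,
                 subset_by: str | None = None, spread_limit: float = 1.0):
        self.efficiencies = efficiencies
        self.group_by = group_by
        self.subset_by = subset_by
        self.spread_limit = spread_limit

    def fit(self, X, y=None):
        groups = None
        self.subset_scores_ = {}
        if isinstance(X, CtTable):
            agg = aggregate_technical_reps(X, spread_limit=self.spread_limit)
            ct = agg.to_wide()
            if self.group_by is not None:
                groups = agg.sample_meta().loc[ct.columns, self.group_by]
            if self.subset_by is not None:
                rep = subset_stability(
                    X, efficiencies=self.efficiencies, partition=self.subset_by,
                    groups_key=self.group_by, spread_limit=self.spread_limit,
                )
                self.subset_scores_ = rep.subset_scores
        elif isinstance(X, pd.DataFrame):
            if self.group_by is not None or self.subset_by is not None:
                raise ValidationError(
                    "group_by/subset_by need a CtTable with sample metadata"
                )
            ct = X
        else:
            raise TypeError(f"expected CtTable or DataFrame, got {type(X).__name__}")
        self.ct_ = ct
        self.quantities_ = relative_quantities(ct, self.efficiencies)
        self.scores_ = stability_scores(ct, efficiencies=self.efficiencies,
                                        groups=groups)
        self.genorm_ = genorm(self.quantities_)
        self.pairwise_variation_ = genorm_pairwise_variation(
            self.quantities_, self.genorm_.ranking
        )
        self.ranking_ = self.scores_.table["final_rank"]
        return self
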