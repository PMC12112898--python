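"""Independent brute-force reference implementations of the four stability
algorithms, written with explicit Python loops and the stdlib statistics
module so they share no code path with the package's vectorized versions.

All operate on a plain dict gene -> list of per-sample values (Ct or log2
quantities as each method requires).
"""

import math
import statistics


def sd(xs):
    return statistics.stdev(xs)  # n-1 denominator


def genorm_m_oracle(log2q: dict[str, list[float]]) -> dict[str, float]:
    """M_j = mean over k != j of SD_samples(log2 Q_j - log2 Q_k)."""
    genes = list(log2q)
    m = {}
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            diffs = [a - b for a, b in zip(log2q[j], log2q[k])]
            vs.append(sd(diffs))
        m[j] = sum(vs) / len(vs)
    return m


def genorm_pairwise_variation_oracle(
    log2q: dict[str, list[float]], order: list[str]
) -> list[float]:
    """V(n, n+1) for n = 2..G-1 on genes sorted most-stable first."""
    n_samples = len(next(iter(log2q.values())))
    out = []
    for n in range(2, len(order)):
        nf_n = [sum(log2q[g][s] for g in order[:n]) / n for s in range(n_samples)]
        nf_n1 = [sum(log2q[g][s] for g in order[: n + 1]) / (n + 1)
                 for s in range(n_samples)]
        out.append(sd([a - b for a, b in zip(nf_n, nf_n1)]))
    return out


def _residuals(y: dict[str, list[float]]) -> dict[str, list[float]]:
    genes = list(y)
    n = len(y[genes[0]])
    row_mean = {g: sum(y[g]) / n for g in genes}
    col_mean = [sum(y[g][s] for g in genes) / len(genes) for s in range(n)]
    grand = sum(row_mean.values()) / len(genes)
    return {
        g: [y[g][s] - row_mean[g] - col_mean[s] + grand for s in range(n)]
        for g in genes
    }


def _gene_variances(y: dict[str, list[float]]) -> dict[str, float]:
    genes = list(y)
    G = len(genes)
    S = len(y[genes[0]])
    r = _residuals(y)
    d = {g: sum(v * v for v in r[g]) / (S - 1) for g in genes}
    total = sum(d.values())
    return {
        g: max(0.0, G / (G - 2) * (d[g] - total / (G * (G - 1)))) for g in genes
    }


def normfinder_oracle(y: dict[str, list[float]]) -> dict[str, float]:
    """Ungrouped stability: gene-wise residual SD under the additive model."""
    return {g: math.sqrt(v) for g, v in _gene_variances(y).items()}


def normfinder_grouped_oracle(
    y: dict[str, list[float]], labels: list[str]
) -> dict[str, float]:
    """Grouped stability: mean over groups of |shrunken intergroup diff| +
    sqrt(intragroup variance / group size)."""
    genes = list(y)
    G = len(genes)
    group_ids = list(dict.fromkeys(labels))
    K = len(group_ids)
    sigma2, means, sizes = {}, {}, {}
    for gid in group_ids:
        cols = [s for s, lab in enumerate(labels) if lab == gid]
        sizes[gid] = len(cols)
        block = {g: [y[g][s] for s in cols] for g in genes}
        v = _gene_variances(block)
        for g in genes:
            sigma2[(g, gid)] = v[g]
            means[(g, gid)] = sum(block[g]) / len(cols)
    gene_mean = {g: sum(means[(g, gid)] for gid in group_ids) / K for g in genes}
    grp_mean = {gid: sum(means[(g, gid)] for g in genes) / G for gid in group_ids}
    grand = sum(gene_mean.values()) / G
    d = {
        (g, gid): means[(g, gid)] - gene_mean[g] - grp_mean[gid] + grand
        for g in genes
        for gid in group_ids
    }
    gamma2 = sum(v * v for v in d.values()) / ((G - 1) * (K - 1)) - sum(
        sigma2[(g, gid)] / sizes[gid] for g in genes for gid in group_ids
    ) / (G * K)
    gamma2 = max(gamma2, 0.0)
    rho = {}
    for g in genes:
        parts = []
        for gid in group_ids:
            var_term = sigma2[(g, gid)] / sizes[gid]
            shrink = gamma2 / (gamma2 + var_term) if gamma2 + var_term > 0 else 0.0
            parts.append(abs(d[(g, gid)] * shrink) + math.sqrt(var_term))
        rho[g] = sum(parts) / K
    return rho


def bestkeeper_oracle(ct: dict[str, list[float]]) -> dict[str, dict[str, float]]:
    genes = list(ct)
    n = len(ct[genes[0]])
    index = [
        math.exp(sum(math.log(ct[g][s]) for g in genes) / len(genes))
        for s in range(n)
    ]
    out = {}
    for g in genes:
        xs = ct[g]
        mean = sum(xs) / n
        s = sd(xs)
        if s > 0 and sd(index) > 0:
            mi = sum(index) / n
            cov = sum((x - mean) * (i - mi) for x, i in zip(xs, index)) / (n - 1)
            r = cov / (s * sd(index))
        else:
            r = float("nan")
        out[g] = {"sd": s, "cv_pct": 100.0 * s / mean, "r": r}
    return out


def delta_ct_oracle(ct: dict[str, list[float]]) -> dict[str, float]:
    genes = list(ct)
    out = {}
    for g in genes:
        sds = []
        for k in genes:
            if k == g:
                continue
            sds.append(sd([a - b for a, b in zip(ct[g], ct[k])]))
        out[g] = sum(sds) / len(sds)
    return out
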