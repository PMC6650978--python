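"""Expression meta-analysis: filtering, TMM + precision-weight normalisation,
empirical-Bayes moderated-t differential expression, and downstream summaries.

The normalisation follows the trimmed-mean-of-M-values (TMM) scheme for
library composition and a voom-style mean-variance precision weighting of
log-CPM values.  Differential expression uses the moderated t-statistic:
per-gene residual variances are shrunk toward a prior estimated by the
method of moments on log-variances under a scaled-F model, adding the prior
degrees of freedom to the test.  Genes with |log2 fold change| > 1 and
Benjamini-Hochberg adjusted p < 0.05 (both strict) are called DEGs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import average as upgma_linkage
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import pdist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .homoeology import HomoeologGroup
from .models import ExpressionSampleMeta

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) plus per-sample metadata."""

    counts: pd.DataFrame
    samples: list[ExpressionSampleMeta]

    def __post_init__(self) -> None:
        if list(self.counts.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("count columns must match sample metadata order")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.samples)


@dataclass
class NormalizedMatrix:
    """log2-CPM values with their TMM factors and optional precision weights."""

    logcpm: pd.DataFrame
    tmm_factors: np.ndarray
    lib_sizes: np.ndarray
    weights: pd.DataFrame | None = None


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0).astype(float)
    return counts / lib * 1e6


def filter_low_expression(
    matrix: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in at least min_samples samples."""
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("empty count matrix")
    if min_samples > matrix.n_samples:
        raise ValueError("min_samples exceeds the number of samples")
    keep = (cpm(matrix.counts) >= min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(matrix.counts.loc[keep], matrix.samples)


def tmm_factors(
    matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalisation factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions.  For each sample, M (log ratio)
    and A (log abundance) values over doubly-positive genes are trimmed
    (top/bottom trim_m of M, trim_a of A) and the factor is 2 to the
    inverse-variance-weighted mean of the remaining M values.
    """
    counts = matrix.counts.values.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("library with all-zero counts")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f75 = np.array(
            [np.percentile(counts[:, j][counts[:, j] > 0], 75) for j in range(counts.shape[1])]
        ) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(counts.shape[1])
    yr = counts[:, ref]
    nr = lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        yj = counts[:, j]
        nj = lib[j]
        pos = (yj > 0) & (yr > 0)
        if pos.sum() < 10:
            continue
        pj, pr = yj[pos] / nj, yr[pos] / nr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        # asymptotic (delta-method) variance of M
        v = (nj - yj[pos]) / (nj * yj[pos]) + (nr - yr[pos]) / (nr * yr[pos])
        if np.allclose(m, m[0]):
            factors[j] = 2.0 ** m[0]
            continue
        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(
    matrix: CountMatrix, factors: np.ndarray | None = None, prior_count: float = 0.5
) -> NormalizedMatrix:
    """log2((count + prior) / (libsize*factor + 2*prior) * 1e6)."""
    counts = matrix.counts.values.astype(float)
    lib = counts.sum(axis=0)
    if factors is None:
        factors = np.ones(counts.shape[1])
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise ValueError("TMM factors must be positive")
    eff = lib * factors
    vals = np.log2((counts + prior_count) / (eff + 2 * prior_count)[None, :] * 1e6)
    df = pd.DataFrame(vals, index=matrix.counts.index, columns=matrix.counts.columns)
    return NormalizedMatrix(logcpm=df, tmm_factors=factors, lib_sizes=lib)


def _group_design(groups: list[str]) -> tuple[np.ndarray, list[str]]:
    levels = list(dict.fromkeys(groups))
    design = np.zeros((len(groups), len(levels)))
    for i, g in enumerate(groups):
        design[i, levels.index(g)] = 1.0
    return design, levels


def voom_weights(
    normalized: NormalizedMatrix,
    groups: list[str],
    span: float = 0.5,
    iterations: int = 2,
) -> pd.DataFrame:
    """Mean-variance precision weights for the log-CPM matrix.

    Per gene, residual standard deviations around group means are computed;
    sqrt(sd) is smoothed against average log2 count with a lowess trend, and
    each cell's weight is (trend at its fitted log-count)^-4.  A degenerate
    trend falls back to unit weights (logged).
    """
    y = normalized.logcpm.values
    design, levels = _group_design(groups)
    counts_per_level = design.sum(axis=0)
    if (counts_per_level < 2).all():
        raise ValueError("voom needs at least one group with >= 2 replicates")
    # per-gene group means and residual sd
    group_means = (y @ design) / counts_per_level[None, :]
    fitted = group_means @ design.T
    resid = y - fitted
    df_resid = y.shape[1] - len(levels)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    sd = np.sqrt((resid ** 2).sum(axis=1) / df_resid)
    sqrt_sd = np.sqrt(sd)

    eff = normalized.lib_sizes * normalized.tmm_factors
    # average log2 count per gene (log-cpm re-expressed on the count scale)
    mean_logcount = y.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    ok = np.isfinite(sqrt_sd) & (sd > 0)
    if ok.sum() < 10 or np.ptp(mean_logcount[ok]) < 1e-8:
        logger.warning("voom trend degenerate; falling back to unit weights")
        w = np.ones_like(y)
        return pd.DataFrame(w, index=normalized.logcpm.index, columns=normalized.logcpm.columns)
    trend = lowess(
        sqrt_sd[ok], mean_logcount[ok], frac=span, it=iterations, return_sorted=True
    )
    tx, ty = trend[:, 0], trend[:, 1]
    # fitted log-count per cell
    cell_logcount = fitted + (np.log2(eff + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(cell_logcount, tx, ty, left=ty[0], right=ty[-1])
    pred = np.clip(pred, 1e-3, None)
    w = pred ** -4.0
    return pd.DataFrame(w, index=normalized.logcpm.index, columns=normalized.logcpm.columns)


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimation of (d0, s0^2) from log residual variances.

    Under the scaled-F model, z = log(s^2) has mean log(s0^2) + psi(d/2) -
    log(d/2) - (psi(d0/2) - log(d0/2)) and variance psi'(d/2) + psi'(d0/2).
    Returns (inf, pooled variance) when the observed spread of z does not
    exceed the sampling variance (all true variances equal).
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e_z = float(z.mean())
    v_z = float(z.var(ddof=1))
    tri_d = float(special.polygamma(1, df / 2.0))
    excess = v_z - tri_d
    digamma_d = float(special.digamma(df / 2.0))
    if excess <= 0:
        s0_sq = float(np.exp(e_z - digamma_d + np.log(df / 2.0)))
        return np.inf, s0_sq
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(
        np.exp(
            e_z
            - digamma_d
            + np.log(df / 2.0)
            + float(special.digamma(d0 / 2.0))
            - np.log(d0 / 2.0)
        )
    )
    return d0, s0_sq


@dataclass
class ContrastResult:
    """Per-gene differential-expression statistics for one two-group contrast."""

    table: pd.DataFrame  # logFC, mean_expr, ordinary_t, moderated_t, p, adjP, is_deg
    contrast: str
    d0: float
    s0_sq: float
    residual_df: float


def moderated_t_test(
    normalized: NormalizedMatrix,
    groups: list[str],
    contrast: tuple[str, str],
    weights: pd.DataFrame | None = None,
    prior_df: float | None = None,
) -> ContrastResult:
    """Two-group moderated t-test on log-CPM values (optionally weighted).

    ``contrast = (test, reference)``; logFC = mean(test) - mean(reference) in
    log2 units.  With the prior degrees of freedom d0 = 0 the moderated t
    reduces exactly to the ordinary two-sample t.
    """
    y = normalized.logcpm.values
    groups = list(groups)
    test_level, ref_level = contrast
    idx_test = np.array([g == test_level for g in groups])
    idx_ref = np.array([g == ref_level for g in groups])
    n1, n2 = int(idx_test.sum()), int(idx_ref.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both contrast groups need >= 2 samples")
    if weights is not None:
        w = weights.values
    else:
        w = np.ones_like(y)
    w = np.where(np.isfinite(w) & (w > 0), w, 0.0)
    sel = idx_test | idx_ref
    yv = y[:, sel]
    wv = w[:, sel]
    grp = idx_test[sel]

    w1 = wv[:, grp].sum(axis=1)
    w2 = wv[:, ~grp].sum(axis=1)
    mean1 = (yv[:, grp] * wv[:, grp]).sum(axis=1) / w1
    mean2 = (yv[:, ~grp] * wv[:, ~grp]).sum(axis=1) / w2
    logfc = mean1 - mean2
    fitted = np.where(grp[None, :], mean1[:, None], mean2[:, None])
    df_resid = n1 + n2 - 2
    s2 = ((yv - fitted) ** 2 * wv).sum(axis=1) / df_resid
    u = 1.0 / w1 + 1.0 / w2  # coefficient variance factor

    with np.errstate(divide="ignore", invalid="ignore"):
        ordinary_t = logfc / np.sqrt(s2 * u)

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s2, df_resid)
    if d0 == 0.0:
        s2_post = s2
        df_total = df_resid
        mod_t = ordinary_t
        p = 2.0 * stats.t.sf(np.abs(mod_t), df=df_total)
        adj = bh_adjust(np.nan_to_num(p, nan=1.0))
        table = pd.DataFrame(
            {
                "logFC": logfc,
                "mean_expr": (mean1 + mean2) / 2.0,
                "ordinary_t": ordinary_t,
                "moderated_t": mod_t,
                "p": p,
                "adjP": adj,
                "is_deg": False,
            },
            index=normalized.logcpm.index,
        )
        return call_degs(
            ContrastResult(
                table=table,
                contrast=f"{test_level}-vs-{ref_level}",
                d0=0.0,
                s0_sq=s0_sq,
                residual_df=df_resid,
            )
        )
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e9
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    if (s2_post <= 0).any():
        raise ValueError("non-positive posterior variance (zero residual df?)")
    mod_t = logfc / np.sqrt(s2_post * u)
    p = 2.0 * stats.t.sf(np.abs(mod_t), df=df_total)
    adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "mean_expr": (mean1 + mean2) / 2.0,
            "ordinary_t": ordinary_t,
            "moderated_t": mod_t,
            "p": p,
            "adjP": adj,
            "is_deg": False,
        },
        index=normalized.logcpm.index,
    )
    result = ContrastResult(
        table=table,
        contrast=f"{test_level}-vs-{ref_level}",
        d0=d0,
        s0_sq=s0_sq,
        residual_df=df_resid,
    )
    return call_degs(result)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    result: ContrastResult, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> ContrastResult:
    """is_deg iff |logFC| > lfc_threshold AND adjP < alpha (both strict)."""
    t = result.table
    t["is_deg"] = (t["logFC"].abs() > lfc_threshold) & (t["adjP"] < alpha)
    return result


def pearson_matrix(
    normalized: NormalizedMatrix, gene_subset: list[str] | None = None
) -> pd.DataFrame:
    """Gene-by-gene Pearson correlation of expression profiles."""
    df = normalized.logcpm
    if gene_subset is not None:
        df = df.loc[[g for g in gene_subset if g in df.index]]
    if df.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    variances = df.var(axis=1)
    zero_var = variances[variances == 0].index
    if len(zero_var):
        logger.warning("excluding %d zero-variance genes from correlation", len(zero_var))
        df = df.drop(index=zero_var)
    mat = np.corrcoef(df.values)
    return pd.DataFrame(mat, index=df.index, columns=df.index)


@dataclass
class Dendrogram:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str] = field(default_factory=list)

    def newick(self) -> str:
        """Nested-parentheses text with branch lengths from merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for i, (a, b, h, _cnt) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + i] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + i] = h
        return node[n + len(self.linkage) - 1] + ";"


def hierarchical_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering of gene profiles: euclidean distance, average
    (UPGMA) linkage; merge heights are non-decreasing."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    dist = pdist(matrix.values, metric="euclidean")
    link = upgma_linkage(dist)
    labels = list(matrix.index)
    order = [labels[i] for i in leaves_list(link)]
    return Dendrogram(linkage=link, labels=labels, leaf_order=order)


@dataclass
class HomoeologExpressionCall:
    group_id: str
    call: str  # similar / partitioned
    silenced_or_divergent: list[str]


def classify_homoeolog_expression(
    group: HomoeologGroup,
    normalized: NormalizedMatrix,
    silence_frac: float = 0.05,
    divergence_lfc: float = 1.0,
) -> HomoeologExpressionCall:
    """Partitioned iff a member is silenced (mean linear expression below
    silence_frac of the group maximum, or absent from the matrix) or any
    member pair differs by more than divergence_lfc in mean log2 expression."""
    if group.kind not in ("triplet", "pair", "probable_triplet", "probable_pair"):
        raise ValueError("expression partitioning needs a multi-member group")
    means: dict[str, float | None] = {}
    for gene_id, _sub in group.members:
        if gene_id in normalized.logcpm.index:
            means[gene_id] = float(np.mean(2.0 ** normalized.logcpm.loc[gene_id].values))
        else:
            means[gene_id] = None  # filtered out = not expressed
    present = {g: m for g, m in means.items() if m is not None}
    flagged: list[str] = [g for g, m in means.items() if m is None]
    if present:
        top = max(present.values())
        for g, m in present.items():
            if m < silence_frac * top:
                flagged.append(g)
        ids = list(present)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = present[ids[i]], present[ids[j]]
                if a > 0 and b > 0 and abs(np.log2(a / b)) > divergence_lfc:
                    for g in (ids[i], ids[j]):
                        if g not in flagged:
                            flagged.append(g)
    call = "partitioned" if flagged else "similar"
    return HomoeologExpressionCall(
        group_id=group.group_id,
        call=call,
        silenced_or_divergent=sorted(flagged) if call == "partitioned" else [],
    )


def categorize_expression_breadth(
    normalized: NormalizedMatrix,
    tissues: list[str],
    floor: float = 1.0,
    specificity_ratio: float = 4.0,
) -> pd.DataFrame:
    """Per-gene breadth category and expression level.

    constitutive: expressed (mean log2-CPM > floor) in every tissue with a
    max/min linear tissue ratio < specificity_ratio; tissue_specific(t):
    expressed in tissue t at >= specificity_ratio times every other tissue;
    otherwise 'other'.  Levels are tertiles of the overall mean among genes
    expressed in at least one tissue; genes below the floor everywhere are
    'weak'.
    """
    unique_tissues = list(dict.fromkeys(tissues))
    if len(unique_tissues) < 2:
        raise ValueError("breadth categories need >= 2 tissues")
    y = normalized.logcpm
    tissue_means = {}
    for t in unique_tissues:
        cols = [c for c, tt in zip(y.columns, tissues) if tt == t]
        tissue_means[t] = y[cols].mean(axis=1)
    tm = pd.DataFrame(tissue_means)
    linear = 2.0 ** tm
    expressed = tm > floor
    categories = []
    for gid in y.index:
        row_lin = linear.loc[gid]
        row_exp = expressed.loc[gid]
        if row_exp.all() and row_lin.max() / row_lin.min() < specificity_ratio:
            categories.append("constitutive")
            continue
        specific = None
        for t in unique_tissues:
            others = [o for o in unique_tissues if o != t]
            if row_exp[t] and all(
                row_lin[t] >= specificity_ratio * row_lin[o] for o in others
            ):
                specific = t
                break
        categories.append(f"tissue_specific({specific})" if specific else "other")
    overall = y.mean(axis=1)
    any_expressed = expressed.any(axis=1)
    levels = pd.Series("weak", index=y.index, dtype=object)
    if any_expressed.sum() >= 3:
        vals = overall[any_expressed]
        t1, t2 = np.quantile(vals, [1 / 3, 2 / 3])
        for gid in vals.index:
            v = overall[gid]
            levels[gid] = "weak" if v <= t1 else ("moderate" if v <= t2 else "high")
    return pd.DataFrame(
        {"category": categories, "level": levels, "mean_logcpm": overall}, index=y.index
    )
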