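"""Cohort-level statistics over the alteration matrix.

Builds the samples x genes categorical alteration matrix from per-sample
variant and copy-number calls, tests per-gene enrichment between the two
HPV strata (Pearson chi-squared with Benjamini-Hochberg FDR control),
tests clinical covariates (Wilcoxon rank sum for ordinal covariates,
logistic regression for age), clusters samples on their binarised
alteration profiles (Jaccard distance, average linkage), and evaluates the
design's chi-squared power at a given Cohen's w effect size.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = [
    "AlterationMatrix", "EnrichmentResult", "ClusteringResult", "PowerSpec",
    "build_alteration_matrix", "gene_enrichment", "chi_squared_test",
    "fisher_exact", "wilcoxon_rank_sum", "logistic_group_test", "bh_fdr",
    "hierarchical_cluster", "chi_squared_power", "CohortModel", "CohortResults",
]

CATEGORIES = ("none", "mutation", "amplification", "deletion", "multiple")


@dataclass
class AlterationMatrix:
    """Samples x genes categorical matrix plus per-sample group labels."""

    data: pd.DataFrame  # index: samples; columns: genes; values in CATEGORIES
    groups: pd.Series  # index: samples; values e.g. "A"/"B"

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(np.unique(self.data.to_numpy())) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown alteration categories: {bad}")

    @property
    def binary(self) -> pd.DataFrame:
        """1 where the sample carries any alteration in the gene."""
        return (self.data != "none").astype(int)

    @property
    def altered_genes(self) -> list[str]:
        b = self.binary
        return [g for g in b.columns if b[g].sum() > 0]


@dataclass
class EnrichmentResult:
    gene: str
    table: np.ndarray  # 2x2: rows groups, cols altered/unaltered
    statistic: float
    p_value: float
    q_value: float = float("nan")


@dataclass
class ClusteringResult:
    distances: np.ndarray  # square form
    linkage: np.ndarray
    labels: np.ndarray  # two-group cut, values {1, 2}
    crosstab: pd.DataFrame
    purity: float
    degenerate: bool = False
    sample_names: list | None = None

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        ids = self.sample_names or [str(i) for i in range(len(self.labels))]
        tree = TreeNode.from_linkage_matrix(self.linkage, ids)
        return str(tree)


@dataclass
class PowerSpec:
    effect_size_w: float = 0.5
    alpha: float = 0.05
    n_total: int = 40
    df: int = 1

    def __post_init__(self) -> None:
        if self.effect_size_w < 0:
            raise ValueError("Cohen's w must be non-negative")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")


def build_alteration_matrix(variant_calls: dict, cna_calls: dict,
                            sample_sheet: pd.DataFrame,
                            genes: list | None = None) -> AlterationMatrix:
    """Gene-level reduction of per-sample calls.

    ``variant_calls`` maps sample -> iterable of objects/dicts with a
    ``gene`` attribute (or key); ``cna_calls`` likewise with ``gene`` and
    ``kind``.  A sample-gene hit by both a mutation and a CNA becomes
    ``multiple``.  ``sample_sheet`` needs columns ``sample`` and ``group``.
    """
    samples = list(sample_sheet["sample"])
    known = set(samples)
    for src in (variant_calls, cna_calls):
        unknown = set(src) - known
        if unknown:
            raise ValueError(f"calls for samples not in sheet: {sorted(unknown)}")
    if genes is None:
        genes = sorted(
            {_get(c, "gene") for calls in variant_calls.values() for c in calls}
            | {_get(c, "gene") for calls in cna_calls.values() for c in calls}
        )
    data = pd.DataFrame("none", index=samples, columns=list(genes))
    for sample, calls in variant_calls.items():
        for c in calls:
            g = _get(c, "gene")
            if g in data.columns:
                data.loc[sample, g] = "mutation"
    for sample, calls in cna_calls.items():
        for c in calls:
            g = _get(c, "gene")
            if g not in data.columns:
                continue
            kind = ("amplification" if _get(c, "kind") == "amplification"
                    else "deletion")
            data.loc[sample, g] = ("multiple" if data.loc[sample, g] == "mutation"
                                   else kind)
    groups = sample_sheet.set_index("sample")["group"]
    return AlterationMatrix(data, groups)


def _get(obj, attr):
    return obj[attr] if isinstance(obj, dict) else getattr(obj, attr)


def chi_squared_test(table, correction: bool = False):
    """Pearson chi-squared on a 2x2 table; Yates correction off by default.

    Degenerate tables (a zero row/column margin) return statistic 0, p = 1.
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("table must be non-negative with positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p (hypergeometric tail summation)."""
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("table must be non-negative")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def _rank_sum_stat(x, y):
    """Mid-rank sum of x within the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    return float(ranks[: len(x)].sum()), ranks


def wilcoxon_rank_sum(x, y, exact_limit: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p with mid-ranks for ties.

    Exact null by enumeration over all C(n+m, n) group assignments when
    n + m <= ``exact_limit``; otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    w_obs, ranks = _rank_sum_stat(x, y)
    if n + m <= exact_limit:
        idx = range(n + m)
        mean_w = n * (n + m + 1) / 2.0
        dev_obs = abs(w_obs - mean_w)
        count = total = 0
        for comb in itertools.combinations(idx, n):
            w = ranks[list(comb)].sum()
            total += 1
            if abs(w - mean_w) >= dev_obs - 1e-9:
                count += 1
        return count / total
    mu = n * (n + m + 1) / 2.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    tie_term = ((tie_counts ** 3 - tie_counts).sum()
                / ((n + m) * (n + m - 1.0)))
    var = n * m / 12.0 * (n + m + 1.0 - tie_term)
    if var <= 0:
        return 1.0
    z = (w_obs - mu) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def logistic_group_test(covariate, group):
    """Single-covariate logistic regression of group membership.

    Returns ``(coefficient, p)`` with a Wald test on the slope; under
    perfect separation the fit is flagged by returning ``p = nan``.
    """
    x = np.asarray(covariate, dtype=float)
    labels = pd.Series(group)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    y = (labels == uniq[1]).astype(float).to_numpy()
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need >= 3 samples per group")
    # perfect separation: a threshold on x splits the groups exactly
    x0, x1 = x[y == 0], x[y == 1]
    if x0.max() < x1.min():
        return math.inf, float("nan")
    if x1.max() < x0.min():
        return -math.inf, float("nan")
    X = sm.add_constant(x)
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    return float(fit.params[1]), float(fit.pvalues[1])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_enrichment(matrix: AlterationMatrix) -> list[EnrichmentResult]:
    """Per-gene two-group enrichment with FDR control across tested genes.

    Only genes altered in at least one sample are tested; q-values are BH
    across that set; results sorted by q then p.
    """
    groups = sorted(matrix.groups.unique())
    if len(groups) < 2:
        raise ValueError("enrichment needs two non-empty groups")
    b = matrix.binary
    results = []
    for gene in matrix.altered_genes:
        tab = np.array([
            [int(b.loc[matrix.groups == g, gene].sum()),
             int((matrix.groups == g).sum() - b.loc[matrix.groups == g, gene].sum())]
            for g in groups
        ])
        stat, p = chi_squared_test(tab)
        results.append(EnrichmentResult(gene, tab, stat, p))
    if results:
        q = bh_fdr([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    results.sort(key=lambda r: (r.q_value, r.p_value, r.gene))
    return results


def hierarchical_cluster(matrix: AlterationMatrix, metric: str = "hamming",
                         method: str = "ward") -> ClusteringResult:
    """Hierarchical clustering on distances between binary alteration profiles.

    Defaults: Hamming distance, Ward linkage.  On a sparse gene panel the
    shared *absence* of alterations is informative (Hamming counts it,
    Jaccard does not), and samples with few or no alterations sit at Jaccard
    distance ~1 from everyone, so average linkage cuts them off as a cluster
    of their own; Ward's variance criterion on Hamming geometry absorbs them
    into the nearest biological group instead.  Both knobs are configurable
    (``metric="jaccard"``, ``method="average"`` give the other common
    convention).

    The tree is cut into two groups and cross-tabulated against the HPV
    labels; purity is the fraction of samples on the majority side of the
    best cluster-to-group assignment.  All-identical profiles are flagged
    degenerate (no meaningful two-group cut exists).
    """
    b = matrix.binary
    if len(b) < 2:
        raise ValueError("clustering needs >= 2 samples")
    X = b.to_numpy(dtype=bool)
    degenerate = bool((X == X[0]).all())
    with np.errstate(invalid="ignore"):
        d = pdist(X, metric=metric)
    d = np.nan_to_num(d, nan=0.0)  # pairs of all-zero profiles are identical
    Z = hierarchy.linkage(d, method=method)
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    ct = pd.crosstab(pd.Series(labels, index=b.index, name="cluster"),
                     matrix.groups.rename("group"))
    # purity under the better of the two cluster->group assignments
    m = ct.to_numpy()
    if m.shape == (2, 2):
        purity = max(m[0, 0] + m[1, 1], m[0, 1] + m[1, 0]) / m.sum()
    else:
        purity = m.max(axis=1).sum() / m.sum()
    return ClusteringResult(squareform(d), Z, labels, ct, float(purity),
                            degenerate, sample_names=list(b.index))


def chi_squared_power(spec: PowerSpec) -> float:
    """Power of the chi-squared test at effect size w: the noncentral
    chi-squared (ncp = N * w^2) mass beyond the central critical value."""
    crit = stats.chi2.ppf(1.0 - spec.alpha, spec.df)
    lam = spec.n_total * spec.effect_size_w ** 2
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncx2.sf(crit, spec.df, lam))


class CohortModel:
    """Model interface: alteration matrix in, enrichment + clustering out."""

    def __init__(self, matrix: AlterationMatrix, clinical: pd.DataFrame | None = None):
        self.matrix = matrix
        self.clinical = clinical

    @classmethod
    def from_calls(cls, variant_calls, cna_calls, sample_sheet, **kw):
        return cls(build_alteration_matrix(variant_calls, cna_calls, sample_sheet),
                   clinical=kw.pop("clinical", None))

    def fit(self) -> "CohortResults":
        enrichment = gene_enrichment(self.matrix)
        clustering = hierarchical_cluster(self.matrix) if len(self.matrix.data) > 1 else None
        clinical_tests = {}
        if self.clinical is not None:
            cl = self.clinical.set_index("sample").loc[self.matrix.data.index]
            grp = self.matrix.groups
            for col in cl.columns:
                vals = cl[col]
                if not np.issubdtype(vals.dtype, np.number):
                    continue
                a = vals[grp == sorted(grp.unique())[0]].dropna()
                b = vals[grp == sorted(grp.unique())[1]].dropna()
                if col.lower() == "age":
                    coef, p = logistic_group_test(vals.dropna(),
                                                  grp.loc[vals.dropna().index])
                    clinical_tests[col] = {"test": "logistic", "coef": coef, "p": p}
                elif len(a) and len(b):
                    p = wilcoxon_rank_sum(a.to_numpy(), b.to_numpy())
                    clinical_tests[col] = {"test": "wilcoxon", "p": p}
            if clinical_tests:
                q = bh_fdr([t["p"] for t in clinical_tests.values()])
                for t, qv in zip(clinical_tests.values(), q):
                    t["q"] = float(qv)
        return CohortResults(self, enrichment, clustering, clinical_tests)


class CohortResults:
    def __init__(self, model, enrichment, clustering, clinical_tests):
        self.model = model
        self.enrichment = enrichment
        self.clustering = clustering
        self.clinical_tests = clinical_tests

    @property
    def enrichment_table(self) -> pd.DataFrame:
        rows = []
        for r in self.enrichment:
            (a1, a0), (b1, b0) = r.table
            rows.append({"gene": r.gene, "altered_a": a1, "unaltered_a": a0,
                         "altered_b": b1, "unaltered_b": b0,
                         "chi2": r.statistic, "p": r.p_value, "q": r.q_value})
        return pd.DataFrame(rows, columns=["gene", "altered_a", "unaltered_a",
                                           "altered_b", "unaltered_b",
                                           "chi2", "p", "q"])

    def summary(self) -> str:
        lines = ["Cohort analysis", ""]
        et = self.enrichment_table
        if len(et):
            lines.append("Gene enrichment (chi-squared, BH-FDR):")
            lines.append(et.to_string(index=False))
        if self.clustering is not None:
            lines += ["", f"Clustering purity vs labels: {self.clustering.purity:.3f}",
                      self.clustering.crosstab.to_string()]
        for name, t in self.clinical_tests.items():
            lines.append(f"clinical {name}: {t}")
        return "\n".join(lines)
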