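"""Cohort statistics: volcano classification, group tests with a normality
gate, marker regression, pathway shares, clustering/PCA and the pairwise
correlation ledger.

Conventions follow common label-free proteomics practice: fold changes are
linear-scale ratios of group means, per-protein p-values come from a Welch
t-test on log2 intensities, and significance is judged at raw p < 0.05
(Benjamini-Hochberg available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as _PCA
from statsmodels.stats.multitest import multipletests

from .instantiate import ProteinAbundanceMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# volcano
# ---------------------------------------------------------------------------


@dataclass
class VolcanoResult:
    table: pd.DataFrame  # index protein; columns log2_fc, p_value, class
    fraction_up: float
    fraction_down: float
    n_tested: int


def classify_fold_change(
    fc: float, p: float, fc_low: float = 0.5, fc_high: float = 2.0, alpha: float = 0.05
) -> str:
    """Volcano class of one (linear fold change, p) pair.

    down iff FC < fc_low and p < alpha; up iff FC > fc_high and p < alpha;
    otherwise unchanged.  The partition is exhaustive and exclusive.
    """
    if np.isfinite(fc) and np.isfinite(p) and p < alpha:
        if fc < fc_low:
            return "down"
        if fc > fc_high:
            return "up"
    return "unchanged"


def volcano(
    matrix: ProteinAbundanceMatrix,
    group_a: str,
    group_b: str,
    subset: Sequence[str] | None = None,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    alpha: float = 0.05,
) -> VolcanoResult:
    """Per-protein fold change (mean(B)/mean(A), linear scale) and Welch
    t-test p on log2 intensities; classes and regulated fractions over
    `subset` (default: all proteins)."""
    sa = matrix.samples_in_group(group_a)
    sb = matrix.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("volcano needs >= 2 samples per group")
    proteins = matrix.proteins if subset is None else [p for p in subset if p in matrix.intensity.index]
    if subset is not None and not proteins:
        logger.warning("volcano subset disjoint from matrix: empty result")
        empty = pd.DataFrame(columns=["log2_fc", "p_value", "class"])
        return VolcanoResult(table=empty, fraction_up=0.0, fraction_down=0.0, n_tested=0)
    A = matrix.intensity.loc[proteins, sa].to_numpy(float)
    B = matrix.intensity.loc[proteins, sb].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.nanmean(B, axis=1) / np.nanmean(A, axis=1)
        la, lb = np.log2(A), np.log2(B)
        t, p = sps.ttest_ind(lb, la, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, float)
    # at least two values per group are required for a test
    enough = (np.sum(np.isfinite(la), axis=1) >= 2) & (np.sum(np.isfinite(lb), axis=1) >= 2)
    p[~enough] = np.nan
    classes = [
        classify_fold_change(f, q, fc_low, fc_high, alpha) for f, q in zip(fc, p)
    ]
    table = pd.DataFrame(
        {"log2_fc": np.log2(fc), "p_value": p, "class": classes}, index=proteins
    )
    tested = int(np.sum(np.isfinite(p)))
    n = len(proteins)
    return VolcanoResult(
        table=table,
        fraction_up=sum(c == "up" for c in classes) / n if n else 0.0,
        fraction_down=sum(c == "down" for c in classes) / n if n else 0.0,
        n_tested=tested,
    )


# ---------------------------------------------------------------------------
# group comparison with normality gate
# ---------------------------------------------------------------------------


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    test_used: str  # "t-test" | "rank-test"
    normality_p: tuple[float, float]


def _ks_normality_p(x: np.ndarray) -> float:
    """One-sample KS test of standardized values against the normal law."""
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0  # degenerate: constant values are not normal
    z = (x - x.mean()) / sd
    return float(sps.kstest(z, "norm").pvalue)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
    alpha_norm: float = 0.05,
) -> GroupTestResult:
    """Two-group comparison with a Kolmogorov-Smirnov normality gate.

    If both groups pass the normality check, an unpaired two-sided Student
    t-test is used; otherwise the two-sample rank-sum (Mann-Whitney) test.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("compare_groups needs n >= 3 per group")
    pa, pb = _ks_normality_p(a), _ks_normality_p(b)
    if pa >= alpha_norm and pb >= alpha_norm:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        used = "t-test"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        used = "rank-test"
    return GroupTestResult(
        statistic=float(stat), p_value=float(p), test_used=used, normality_p=(pa, pb)
    )


# ---------------------------------------------------------------------------
# marker regression
# ---------------------------------------------------------------------------


@dataclass
class MarkerRegressionResult:
    pathway: str
    table: pd.DataFrame  # index protein; columns slope, r2, p_value
    n_significant: int
    n_total: int
    skipped: list[str] = field(default_factory=list)


def marker_regression(
    capacity: pd.Series,
    matrix: ProteinAbundanceMatrix,
    pathway_proteins: Sequence[str],
    alpha: float = 0.05,
    pathway: str = "",
    bh_correct: bool = False,
) -> MarkerRegressionResult:
    """Per-protein OLS of a pathway capacity on protein abundance.

    Counts proteins significantly associated with the capacity of their
    pathway (raw p < alpha by default; Benjamini-Hochberg behind a flag).
    """
    proteins = [p for p in pathway_proteins if p in matrix.intensity.index]
    rows = []
    skipped = []
    for prot in proteins:
        x = matrix.intensity.loc[prot, capacity.index].to_numpy(float)
        y = capacity.to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 4:
            skipped.append(prot)
            continue
        if np.ptp(x[ok]) == 0:
            skipped.append(prot)
            logger.info("marker %s skipped: constant abundance", prot)
            continue
        res = sps.linregress(x[ok], y[ok])
        rows.append((prot, res.slope, res.rvalue**2, res.pvalue))
    table = pd.DataFrame(
        rows, columns=["protein", "slope", "r2", "p_value"]
    ).set_index("protein")
    pvals = table["p_value"].to_numpy()
    if bh_correct and len(pvals):
        sig = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        sig = pvals < alpha
    return MarkerRegressionResult(
        pathway=pathway,
        table=table,
        n_significant=int(np.sum(sig)),
        n_total=len(table),
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# pathway scores and score-capacity regression
# ---------------------------------------------------------------------------


def pathway_score(
    matrix: ProteinAbundanceMatrix, protein_set: Sequence[str]
) -> pd.Series:
    """Per-sample share of total intensity carried by a protein set."""
    present = [p for p in protein_set if p in matrix.intensity.index]
    if not present:
        raise ValueError("protein set has no overlap with the matrix")
    num = matrix.intensity.loc[present].sum(axis=0, skipna=True)
    den = matrix.intensity.sum(axis=0, skipna=True)
    return num / den


def pathway_zscore_means(
    matrix: ProteinAbundanceMatrix, protein_set: Sequence[str]
) -> pd.DataFrame:
    """Per-protein z-scored intensities for heatmap-style export."""
    present = [p for p in protein_set if p in matrix.intensity.index]
    if not present:
        raise ValueError("protein set has no overlap with the matrix")
    sub = matrix.intensity.loc[present]
    return sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)


def score_capacity_regression(
    score: pd.Series, capacities: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """OLS of a per-sample pathway score against each capacity column.

    Returns one row per capacity with slope, R^2, p and a significance flag.
    """
    rows = []
    for col in capacities.columns:
        y = score.reindex(capacities.index).to_numpy(float)
        x = capacities[col].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 4 or np.ptp(x[ok]) == 0:
            rows.append((col, np.nan, np.nan, np.nan, False))
            continue
        res = sps.linregress(x[ok], y[ok])
        rows.append((col, res.slope, res.rvalue**2, res.pvalue, res.pvalue < alpha))
    return pd.DataFrame(
        rows, columns=["capacity", "slope", "r2", "p_value", "significant"]
    ).set_index("capacity")


# ---------------------------------------------------------------------------
# correlation ledger
# ---------------------------------------------------------------------------


@dataclass
class CorrelationLedger:
    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame  # boolean, significant at alpha
    signed: pd.DataFrame  # -1 / 0 / +1
    n: pd.DataFrame  # pairwise-complete n
    provenance: dict[str, str] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def correlation_ledger(
    features: pd.DataFrame,
    alpha: float = 0.05,
    provenance: Mapping[str, str] | None = None,
) -> CorrelationLedger:
    """Pairwise Pearson correlations over per-sample features.

    Missing values are handled pairwise-complete; zero-variance features are
    excluded with a note.  The signed matrix is -1/0/+1 at significance
    `alpha`.
    """
    if len(features) < 4:
        raise ValueError("correlation ledger needs >= 4 samples")
    excluded = [
        c
        for c in features.columns
        if features[c].dropna().nunique() <= 1
    ]
    if excluded:
        logger.info("correlation ledger excluded zero-variance features: %s", excluded)
    cols = [c for c in features.columns if c not in excluded]
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), int)
    for i in range(k):
        n[i, i] = features[cols[i]].notna().sum()
        for j in range(i + 1, k):
            x = features[cols[i]].to_numpy(float)
            y = features[cols[j]].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < 4 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = sps.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    mask = (pdf < alpha) & np.isfinite(rdf)
    np.fill_diagonal(mask.values, False)
    signed = pd.DataFrame(
        np.where(mask, np.sign(rdf), 0.0).astype(int), index=cols, columns=cols
    )
    return CorrelationLedger(
        r=rdf,
        p=pdf,
        mask=mask,
        signed=signed,
        n=pd.DataFrame(n, index=cols, columns=cols),
        provenance=dict(provenance or {}),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# z-score clustering and PCA
# ---------------------------------------------------------------------------


def zscore(df: pd.DataFrame, axis: int = 1) -> pd.DataFrame:
    """Transform each feature to mean 0, sd 1 (row-wise by default)."""
    if axis == 1:
        return df.sub(df.mean(axis=1), axis=0).div(df.std(axis=1, ddof=1), axis=0)
    return (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    dropped: list[str]


def zscore_cluster(
    matrix: ProteinAbundanceMatrix | pd.DataFrame,
    subset: Sequence[str] | None = None,
) -> ClusterResult:
    """Agglomerative clustering (average linkage, Euclidean) of z-scored
    features; constant features are dropped with a note."""
    df = matrix.intensity if isinstance(matrix, ProteinAbundanceMatrix) else matrix
    if subset is not None:
        df = df.loc[[p for p in subset if p in df.index]]
    dropped = list(df.index[df.std(axis=1, ddof=1).fillna(0.0) == 0])
    if dropped:
        logger.info("clustering dropped constant features: %s", dropped[:10])
    df = df.drop(index=dropped)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("clustering needs >= 2 rows and >= 2 columns")
    z = zscore(df).fillna(0.0)
    row_link = hierarchy.linkage(pdist(z.to_numpy()), method="average")
    col_link = hierarchy.linkage(pdist(z.to_numpy().T), method="average")
    row_order = [df.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [df.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        dropped=dropped,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray


def pca(
    matrix: ProteinAbundanceMatrix | pd.DataFrame,
    subset: Sequence[str] | None = None,
    n_components: int = 2,
) -> PCAResult:
    """PCA of samples in z-scored feature space.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive (deterministic across library versions).
    """
    df = matrix.intensity if isinstance(matrix, ProteinAbundanceMatrix) else matrix
    if subset is not None:
        df = df.loc[[p for p in subset if p in df.index]]
    df = df[df.std(axis=1, ddof=1).fillna(0.0) > 0]
    z = zscore(df).fillna(0.0)
    X = z.to_numpy().T  # samples x features
    n_components = min(n_components, min(X.shape) - 1) or 1
    model = _PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=df.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )
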