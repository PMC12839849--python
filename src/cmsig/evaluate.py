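"""Group-level statistics linking risk groups back to subtype biology.

Covers the downstream validation analyses: hypergeometric subtype
enrichment of the high-risk group (with a Haldane-Anscombe-corrected odds
ratio), Wilcoxon / chi-square / Fisher group comparisons, ssGSEA immune
infiltration contrasts across 28 immune-cell programs, and Pearson
correlation maps between (radiomic) features and pathway enrichment scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NOLBL, ClinicalTable, ExpressionMatrix, GeneSetCollection
from .risk import HIGH, LOW
from .spectra import ssgsea_spectra


@dataclass
class EnrichmentResult:
    """Subtype enrichment of one group: OR and one-sided hypergeometric p."""

    odds_ratio: float
    p: float
    table: np.ndarray  # the collapsed 2x2 [[high_target, high_other], [low_target, low_other]]
    corrected: bool  # whether the +0.5 zero-cell correction was applied


def subtype_enrichment(groups, subtypes, target: str = "CMS4") -> EnrichmentResult:
    """Is ``target`` over-represented in the high-risk group?

    Collapses to a 2x2 table (high/low x target/other, unlabeled samples
    excluded) and reports the cross-product odds ratio (with +0.5 added to
    every cell when any cell is zero) and the one-sided hypergeometric tail
    probability P(X >= observed high-risk target count) under fixed margins.
    """
    groups = np.asarray(groups, dtype=object)
    subtypes = np.asarray(subtypes, dtype=object)
    keep = subtypes != NOLBL
    groups, subtypes = groups[keep], subtypes[keep]
    if target not in set(subtypes):
        raise ValueError(f"target subtype {target!r} absent")
    hi = groups == HIGH
    lo = groups == LOW
    if hi.sum() == 0 or lo.sum() == 0:
        raise ValueError("both risk groups must be non-empty")
    t = subtypes == target
    table = np.array(
        [
            [int((hi & t).sum()), int((hi & ~t).sum())],
            [int((lo & t).sum()), int((lo & ~t).sum())],
        ]
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("zero margin in the collapsed 2x2 table")
    corrected = bool((table == 0).any())
    ct = table + 0.5 if corrected else table
    odds_ratio = float(ct[0, 0] * ct[1, 1] / (ct[0, 1] * ct[1, 0]))
    # hypergeometric tail: draw n_high samples from N with K targets
    N = int(table.sum())
    K = int(table[:, 0].sum())
    n = int(table[0].sum())
    k = int(table[0, 0])
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(odds_ratio, min(p, 1.0), table, corrected)


def compare_groups_continuous(values, groups) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of a continuous variable across 2 groups.

    Exact enumeration when both groups have <= 8 observations and there are
    no ties; tie-corrected normal approximation (no continuity correction)
    otherwise. Returns (rank-sum U statistic, two-sided p).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    no_ties = len(np.unique(values)) == len(values)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups_categorical(table) -> tuple[str, float, float]:
    """Chi-square or Fisher router for a 2xC contingency table.

    Pearson chi-square (no continuity correction) when every expected count
    is >= 5; Fisher's exact test otherwise, which is only defined here for
    2x2 tables (a small-count table wider than 2 columns is an error).
    Returns (test name, statistic, p).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2xC table with C >= 2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    expected = stats.contingency.expected_freq(table)
    if np.all(expected >= 5):
        res = stats.chi2_contingency(table, correction=False)
        return "chi-square", float(res.statistic), float(res.pvalue)
    if table.shape[1] != 2:
        raise ValueError(
            "expected counts below 5 in a table wider than 2x2: "
            "Fisher's exact test is only supported for 2x2"
        )
    odds, p = stats.fisher_exact(table.astype(int))
    return "fisher", float(odds), float(p)


@dataclass
class InfiltrationResult:
    scores: pd.DataFrame  # samples x cell types (unnormalized ssGSEA)
    contrasts: pd.DataFrame  # per cell type: statistic, p, q, direction


def immune_infiltration(
    expr: ExpressionMatrix,
    immune_sets: GeneSetCollection,
    groups,
    alpha: float = 0.25,
) -> InfiltrationResult:
    """ssGSEA immune-cell scores plus high-vs-low Wilcoxon contrasts.

    Scores are computed with normalization off (they are only compared
    within a cell type across groups); p-values are BH-adjusted across cell
    types.
    """
    spectra = ssgsea_spectra(expr, immune_sets, alpha=alpha, normalize=False)
    scores = spectra.to_frame()
    groups = np.asarray(groups, dtype=object)
    rows = []
    for cell_type in scores.columns:
        stat, p = compare_groups_continuous(scores[cell_type].to_numpy(), groups)
        hi_mean = scores[cell_type].to_numpy()[groups == HIGH].mean()
        lo_mean = scores[cell_type].to_numpy()[groups == LOW].mean()
        rows.append(
            {
                "cell_type": cell_type,
                "statistic": stat,
                "p": p,
                "direction": "high" if hi_mean > lo_mean else "low",
            }
        )
    contrasts = pd.DataFrame(rows).set_index("cell_type")
    contrasts["q"] = multipletests(contrasts["p"].to_numpy(), method="fdr_bh")[1]
    return InfiltrationResult(scores, contrasts)


@dataclass
class CorrelationMap:
    """Feature x pathway Pearson correlations with raw and BH-adjusted p."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    flagged: list[str]  # zero-variance columns excluded from testing


def pathway_feature_correlation(
    features: pd.DataFrame, pathway_scores: pd.DataFrame
) -> CorrelationMap:
    """Pearson r (with two-sided p and BH q) of every feature against every
    pathway enrichment score, on samples shared by both matrices."""
    common = [s for s in features.index if s in set(pathway_scores.index)]
    if len(common) < 3:
        raise ValueError("fewer than 3 shared samples")
    X = features.loc[common]
    Y = pathway_scores.loc[common]
    flagged = [str(c) for c in X.columns if X[c].std() == 0]
    flagged += [str(c) for c in Y.columns if Y[c].std() == 0]
    x_cols = [c for c in X.columns if str(c) not in flagged]
    y_cols = [c for c in Y.columns if str(c) not in flagged]
    if not x_cols or not y_cols:
        raise ValueError("no testable feature/pathway pairs")
    n = len(common)
    Xc = X[x_cols].to_numpy(dtype=float)
    Yc = Y[y_cols].to_numpy(dtype=float)
    Xz = (Xc - Xc.mean(axis=0)) / Xc.std(axis=0)
    Yz = (Yc - Yc.mean(axis=0)) / Yc.std(axis=0)
    r = np.clip(Xz.T @ Yz / n, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.minimum(p, 1.0)
    q = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    return CorrelationMap(
        pd.DataFrame(r, index=x_cols, columns=y_cols),
        pd.DataFrame(p, index=x_cols, columns=y_cols),
        pd.DataFrame(q, index=x_cols, columns=y_cols),
        flagged,
    )
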