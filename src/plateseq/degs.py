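"""Differential expression and cluster-marker statistics.

The DEG test fits, per gene, two nested count GLMs with a per-cell
total-count offset: a null with a single mean and an alternative with
group-specific means.  The difference in deviance between them is referred
to a chi-squared distribution with one degree of freedom.  A fold-change
prefilter (pseudocount 1 on cluster mean expression) is applied before
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .counting import DigitalExpressionMatrix

__all__ = [
    "deg_deviance_test",
    "binomial_marker_test",
    "overlap_with_bulk",
]


def _group_indices(matrix: DigitalExpressionMatrix, cells: Sequence[str]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(matrix.cells)}
    missing = [c for c in cells if c not in lookup]
    if missing:
        raise ValueError(f"cells not in matrix: {missing[:5]}")
    return np.array([lookup[c] for c in cells])


def deg_deviance_test(
    matrix: DigitalExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    family: str = "poisson",
    nb_alpha: float = 0.1,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Deviance-difference test for differential expression between two groups.

    Returns one row per gene with columns ``lr_statistic``, ``p_value``,
    ``fold_change`` ((mean_a + pseudocount)/(mean_b + pseudocount)),
    ``passed_prefilter``, ``fdr`` (BH-adjusted among prefiltered genes) and
    ``significant``.  Genes with zero counts in both groups are excluded and
    listed in ``result.attrs["excluded"]``.

    ``family="nb"`` swaps in a negative binomial GLM with fixed dispersion
    ``nb_alpha``; set ``pseudocount=0`` for the no-pseudocount prefilter
    variant used when comparing against bulk data.
    """
    ia = _group_indices(matrix, group_a)
    ib = _group_indices(matrix, group_b)
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least 2 cells")

    counts = matrix.counts[:, np.concatenate([ia, ib])]
    group = np.r_[np.zeros(len(ia)), np.ones(len(ib))]
    totals = matrix.cell_totals[np.concatenate([ia, ib])].astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cells present; run filter_cells first")
    offset = np.log(totals)
    X_null = np.ones((counts.shape[1], 1))
    X_alt = sm.add_constant(group)

    if family == "poisson":
        fam = sm.families.Poisson()
    elif family == "nb":
        fam = sm.families.NegativeBinomial(alpha=nb_alpha)
    else:
        raise ValueError(f"unknown family {family!r}")

    nonzero = counts.sum(axis=1) > 0
    excluded = [g for g, keep in zip(matrix.genes, nonzero) if not keep]

    mean_a = counts[:, group == 0].mean(axis=1)
    mean_b = counts[:, group == 1].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_change = (mean_a + pseudocount) / (mean_b + pseudocount)

    lr = np.full(len(matrix.genes), np.nan)
    pval = np.full(len(matrix.genes), np.nan)
    import warnings

    with warnings.catch_warnings():
        # degenerate toy genes (e.g. one group all-zero) trip statsmodels'
        # separation warning; the deviance difference is still well defined
        warnings.simplefilter("ignore")
        for gi in np.nonzero(nonzero)[0]:
            y = counts[gi]
            null_fit = sm.GLM(y, X_null, family=fam, offset=offset).fit(tol=1e-12)
            alt_fit = sm.GLM(y, X_alt, family=fam, offset=offset).fit(tol=1e-12)
            stat = max(null_fit.deviance - alt_fit.deviance, 0.0)
            lr[gi] = stat
            pval[gi] = scipy.stats.chi2.sf(stat, df=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        passed = nonzero & (
            np.maximum(fold_change, 1.0 / fold_change) >= fc_threshold
        )
    fdr = np.full(len(matrix.genes), np.nan)
    if passed.any():
        fdr[passed] = multipletests(pval[passed], method=correction)[1]
    significant = passed & (fdr < alpha)

    result = pd.DataFrame(
        {
            "lr_statistic": lr,
            "p_value": pval,
            "fold_change": fold_change,
            "passed_prefilter": passed,
            "fdr": fdr,
            "significant": significant,
        },
        index=matrix.genes,
    )
    result = result.loc[nonzero]
    result.attrs["excluded"] = excluded
    return result


def binomial_marker_test(
    matrix: DigitalExpressionMatrix,
    cluster: Sequence[str],
    rest: Sequence[str],
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Exact binomial test for cluster-specific or cluster-enriched genes.

    Per gene, the number of in-cluster cells detecting it (count > 0) is
    tested against the outside detection fraction as the null probability
    (one-sided, greater).  When the outside fraction is zero but the gene is
    detected inside, the null probability is floored at ``1/(n_outside + 1)``
    and the row is flagged ``floored_null``.
    """
    ic = _group_indices(matrix, cluster)
    ir = _group_indices(matrix, rest)
    if set(ic) & set(ir):
        raise ValueError("cluster and rest must be disjoint")
    if len(ic) < 2 or len(ir) < 2:
        raise ValueError("each group needs at least 2 cells")

    det_in = (matrix.counts[:, ic] > 0).sum(axis=1)
    det_out = (matrix.counts[:, ir] > 0).sum(axis=1)
    n_in, n_out = len(ic), len(ir)
    frac_in = det_in / n_in
    frac_out = det_out / n_out

    pvals = np.ones(len(matrix.genes))
    floored = np.zeros(len(matrix.genes), dtype=bool)
    floor = 1.0 / (n_out + 1)
    for gi in range(len(matrix.genes)):
        p0 = frac_out[gi]
        if p0 == 0.0:
            if det_in[gi] == 0:
                continue
            p0 = floor
            floored[gi] = True
        elif p0 == 1.0:
            pvals[gi] = 1.0
            continue
        pvals[gi] = scipy.stats.binomtest(
            int(det_in[gi]), n_in, p0, alternative="greater"
        ).pvalue
    adjusted = multipletests(pvals, method=correction)[1]
    enriched = (adjusted < alpha) & (frac_in > frac_out)
    return pd.DataFrame(
        {
            "frac_in": frac_in,
            "frac_out": frac_out,
            "p_value": pvals,
            "p_adjusted": adjusted,
            "enriched": enriched,
            "floored_null": floored,
        },
        index=matrix.genes,
    )


@dataclass(frozen=True)
class OverlapResult:
    overlap: int
    only_a: int
    only_b: int
    shared: frozenset


def overlap_with_bulk(deg_single: set, deg_bulk: set) -> OverlapResult:
    """Venn partition between two DEG sets."""
    a, b = set(deg_single), set(deg_bulk)
    inter = a & b
    return OverlapResult(
        overlap=len(inter), only_a=len(a - b), only_b=len(b - a), shared=frozenset(inter)
    )
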