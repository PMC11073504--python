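"""mRNA-protein concordance within and across cell lines.

The central object is the cross-correlation matrix whose (i, j) entry is the
correlation of cell i's mRNA profile with cell j's protein profile over the
shared gene universe.  Diagonal entries are the "same cell" correlations; the
contrast of diagonal vs off-diagonal entries quantifies how much of the
concordance is cell-specific rather than driven by the shared gene-level
abundance hierarchy.

Pearson correlations are computed on log2(x + 1)-transformed abundances by
default (configurable): raw RPKM-like values are heavy-tailed and a linear
correlation on them is dominated by a handful of highly expressed genes.
Spearman correlations act on ranks and ignore the transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .association import ecdf_compare
from .errors import AnalysisError, ParameterError
from .io import AbundanceMatrix, GeneSetCollection, shared_genes
from .summaries import TestSummary

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Cells x cells correlation matrix; rows index mRNA profiles, columns
    protein profiles.  Undefined entries (constant profiles) are NaN."""

    values: pd.DataFrame
    method: str  # pearson | spearman
    n_genes_used: int

    @property
    def cell_ids(self) -> List[str]:
        return list(self.values.index)

    def same_cell(self) -> np.ndarray:
        if not self.values.index.equals(self.values.columns):
            raise AnalysisError("same-cell correlations need matching row/column cells")
        return np.diag(self.values.to_numpy())

    def other_cell(self) -> np.ndarray:
        v = self.values.to_numpy()
        return v[~np.eye(v.shape[0], dtype=bool)]


def _standardize_columns(arr: np.ndarray) -> np.ndarray:
    arr = arr - arr.mean(axis=0, keepdims=True)
    norms = np.sqrt((arr**2).sum(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, arr / norms, np.nan)
    return out


def _prepare(
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    method: str,
    genes: Optional[Sequence[str]],
    log_transform: bool,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"method must be 'pearson' or 'spearman', got {method!r}")
    shared = shared_genes(mrna, protein)
    if genes is not None:
        subset = set(genes)
        shared = [g for g in shared if g in subset]
    if len(shared) < 3:
        raise AnalysisError(f"need >= 3 shared genes, got {len(shared)}")
    x = mrna.data.loc[shared].to_numpy(dtype=float)
    y = protein.data.loc[shared].to_numpy(dtype=float)
    if method == "pearson" and log_transform:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    elif method == "spearman":
        # Pearson on average-rank-transformed columns == Spearman rho
        x = stats.rankdata(x, axis=0)
        y = stats.rankdata(y, axis=0)
    return x, y, shared


def cross_correlation(
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    method: str = "pearson",
    genes: Optional[Sequence[str]] = None,
    log_transform: bool = True,
) -> CorrelationMatrix:
    """All-pairs correlation of mRNA profiles against protein profiles.

    Constant profiles yield NaN entries (flagged undefined, never a silent
    zero).  Protein columns are aligned to the mRNA cell order when the two
    matrices cover the same cells.
    """
    x, y, shared = _prepare(mrna, protein, method, genes, log_transform)
    prot_cells = protein.cell_ids
    if set(prot_cells) == set(mrna.cell_ids) and prot_cells != mrna.cell_ids:
        order = [prot_cells.index(c) for c in mrna.cell_ids]
        y = y[:, order]
        prot_cells = mrna.cell_ids
    r = _standardize_columns(x).T @ _standardize_columns(y)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(
        values=pd.DataFrame(r, index=mrna.cell_ids, columns=prot_cells),
        method=method,
        n_genes_used=len(shared),
    )


def same_vs_other(corr: CorrelationMatrix) -> Tuple[TestSummary, TestSummary]:
    """Contrast diagonal (same-cell) vs off-diagonal correlations.

    Returns a Welch unequal-variance two-sample t (two-sided; the fractional
    degrees of freedom are the Welch-Satterthwaite approximation) and a
    one-sided KS comparison of the two ECDFs, D+ = sup(F_other - F_same),
    which is 1 when every same-cell correlation exceeds every other-cell one.
    """
    if corr.values.shape[0] < 2:
        raise AnalysisError("same_vs_other needs >= 2 cells")
    same = corr.same_cell()
    other = corr.other_cell()
    same = same[np.isfinite(same)]
    other = other[np.isfinite(other)]
    if len(same) < 2 or len(other) < 2:
        raise AnalysisError("too few defined correlations in a group")
    if np.ptp(same) == 0 and np.ptp(other) == 0:
        welch = TestSummary("welch_t", float("nan"), float("nan"), "two_sided",
                            n=(len(same), len(other)))
    else:
        res = stats.ttest_ind(same, other, equal_var=False)
        welch = TestSummary(
            "welch_t", float(res.statistic), float(res.pvalue), "two_sided",
            df=float(res.df), n=(len(same), len(other)),
        )
    ks = ecdf_compare(other, same, alternative="greater")
    return welch, ks


def setwise_correlation(
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    sets: GeneSetCollection,
    method: str = "pearson",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Same-cell correlation restricted to each gene set's members.

    Returns a tidy frame (set_name, cell_id, r, n_genes); sets with fewer
    than 3 members in the shared universe get NaN correlations (flagged).
    """
    x, y, shared = _prepare(mrna, protein, method, None, log_transform)
    pos = {g: i for i, g in enumerate(shared)}
    cells = mrna.cell_ids
    if protein.cell_ids != cells:
        raise AnalysisError("setwise correlations need identical cell panels")
    rows = []
    for name, members in sets.sets.items():
        idx = [pos[g] for g in members if g in pos]
        if len(idx) < 3:
            logger.warning("set %r has %d shared gene(s) < 3; flagged undefined", name, len(idx))
            for cell in cells:
                rows.append((name, cell, np.nan, len(idx)))
            continue
        xs = _standardize_columns(x[idx])
        ys = _standardize_columns(y[idx])
        r = np.clip((xs * ys).sum(axis=0), -1.0, 1.0)
        for cell, value in zip(cells, r):
            rows.append((name, cell, float(value), len(idx)))
    return pd.DataFrame(rows, columns=["set_name", "cell_id", "r", "n_genes"])


def sample_random_set(universe: Sequence[str], n: int, seed: int) -> List[str]:
    """Uniform sample of n genes without replacement; deterministic given seed."""
    if n < 1:
        raise ParameterError(f"random set size must be >= 1, got {n}")
    if n > len(universe):
        raise ParameterError(f"random set size {n} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(universe), size=n, replace=False)
    return [universe[i] for i in idx]


def hallmark_vs_random(
    setwise: pd.DataFrame,
    random_corrs: pd.Series,
    alternative: str = "greater",
) -> Tuple[Dict[str, TestSummary], TestSummary]:
    """Per-hallmark rank-sum tests against the random set, plus a one-way
    ANOVA F across all groups with the random set as reference.

    The rank-sum statistic is the Mann-Whitney U (R's wilcox.test W); exact
    enumeration is used for small tie-free groups, the continuity-corrected
    normal approximation otherwise (scipy's ``method="auto"``).
    """
    rand = random_corrs.to_numpy(dtype=float)
    rand = rand[np.isfinite(rand)]
    if len(rand) < 2:
        raise AnalysisError("random set has < 2 defined correlations")
    per_set: Dict[str, TestSummary] = {}
    groups = []
    for name, grp in setwise.groupby("set_name", sort=False):
        vals = grp["r"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise AnalysisError(f"hallmark {name!r} has < 2 defined correlations")
        u = stats.mannwhitneyu(vals, rand, alternative=alternative, method="auto")
        per_set[name] = TestSummary(
            "wilcoxon_W", float(u.statistic), float(u.pvalue), alternative,
            n=(len(vals), len(rand)),
        )
        groups.append(vals)
    if not groups:
        raise AnalysisError("no hallmark groups provided")
    all_groups = groups + [rand]
    f = stats.f_oneway(*all_groups)
    k = len(all_groups)
    n_total = sum(len(g) for g in all_groups)
    anova = TestSummary(
        "anova_F", float(f.statistic), float(f.pvalue), "two_sided",
        df=(float(k - 1), float(n_total - k)),
    )
    return per_set, anova
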