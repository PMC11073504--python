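"""Associations of the task statistics with division rate and drug response.

Two model families mirror the analysis: Pearson correlations of the delta and
range statistics with growth phenotypes, and linear models of the division
rate on the enrichment delta.  The "fixed effect" is the common slope of an
OLS with hallmark-indicator intercepts (hallmark as a fixed factor); a small
panel of cell lines cannot support random-effect estimation, and a single
pooled slope is what the design calls for.  Per-hallmark slopes come from
separate simple regressions.

``ecdf_compare`` reports the standard two-sample KS statistic D in [0, 1] and,
alongside it, the sample-size-scaled variant sqrt(nm/(n+m)) * D; published
"D" values above 1 can only refer to the scaled form, so both are carried.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ParameterError
from .io import GrowthTable
from .summaries import AssociationRecord, EffectEstimate, TestSummary

logger = logging.getLogger(__name__)


def correlate(
    predictor_values: Sequence[float],
    response_values: Sequence[float],
    predictor: str = "delta",
    response: str = "division_rate",
    hallmark: Optional[str] = None,
) -> AssociationRecord:
    """Pearson r with its two-sided t-based p; incomplete pairs are dropped."""
    x = np.asarray(predictor_values, dtype=float)
    y = np.asarray(response_values, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("predictor and response must be paired (equal length)")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise AnalysisError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationRecord(
            predictor, response, float("nan"), float("nan"), len(x),
            hallmark=hallmark, flagged=True, note="constant variable",
        )
    r, p = stats.pearsonr(x, y)
    return AssociationRecord(predictor, response, float(r), float(p), len(x), hallmark=hallmark)


def _merge_delta_growth(delta_table: pd.DataFrame, growth: GrowthTable) -> pd.DataFrame:
    df = delta_table.merge(
        growth.division_rate.rename("division_rate"),
        left_on="cell_id",
        right_index=True,
        how="inner",
    )
    df = df[np.isfinite(df["delta"]) & np.isfinite(df["division_rate"])]
    if df.empty:
        raise AnalysisError("no overlapping (cell, set) pairs between delta table and growth")
    return df


def fixed_effect_model(delta_table: pd.DataFrame, growth: GrowthTable) -> EffectEstimate:
    """Common slope of division rate on delta with hallmark fixed factors.

    ``delta_table`` is tidy with columns (cell_id, set_name, delta).  The
    design has one intercept per hallmark and a shared delta slope; a design
    in which delta is constant within every hallmark is rank deficient.
    """
    import statsmodels.api as sm

    df = _merge_delta_growth(delta_table, growth)
    if df["set_name"].nunique() < 2:
        raise AnalysisError("fixed-effect model needs >= 2 hallmarks")
    if df["cell_id"].nunique() < 3:
        raise AnalysisError("fixed-effect model needs >= 3 cells")
    dummies = pd.get_dummies(df["set_name"], dtype=float)
    exog = np.column_stack([df["delta"].to_numpy(), dummies.to_numpy()])
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise AnalysisError("rank-deficient design: delta is collinear with hallmark factors")
    fit = sm.OLS(df["division_rate"].to_numpy(), exog).fit()
    ci = fit.conf_int(alpha=0.05)[0]
    return EffectEstimate(
        estimate=float(fit.params[0]),
        std_error=float(fit.bse[0]),
        p_value=float(fit.pvalues[0]),
        model="pooled_fixed_effect",
        n=len(df),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
    )


def per_hallmark_effects(delta_table: pd.DataFrame, growth: GrowthTable) -> List[EffectEstimate]:
    """One OLS slope of division rate on delta per hallmark; hallmarks with
    fewer than 3 complete cells (or constant delta) are skipped with a warning."""
    df = _merge_delta_growth(delta_table, growth)
    out: List[EffectEstimate] = []
    for name, grp in df.groupby("set_name", sort=False):
        if len(grp) < 3:
            logger.warning("hallmark %r has %d cell(s) < 3; skipped", name, len(grp))
            continue
        x = grp["delta"].to_numpy()
        y = grp["division_rate"].to_numpy()
        if np.ptp(x) == 0:
            logger.warning("hallmark %r has constant delta; skipped", name)
            continue
        res = stats.linregress(x, y)
        se = float(res.stderr)
        tcrit = float(stats.t.ppf(0.975, len(grp) - 2))
        out.append(
            EffectEstimate(
                estimate=float(res.slope),
                std_error=se,
                p_value=float(res.pvalue),
                model="per_hallmark",
                n=len(grp),
                hallmark=name,
                ci_low=float(res.slope) - tcrit * se,
                ci_high=float(res.slope) + tcrit * se,
            )
        )
    return out


# ---------------------------------------------------------------------------
# two-sample KS on ECDFs


def ecdf_compare(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two_sided",
) -> TestSummary:
    """Two-sample KS statistic as the supremum ECDF difference.

    ``greater`` tests whether a's ECDF lies above b's: D+ = sup(F_a - F_b);
    ``less`` is the mirror image; ``two_sided`` uses sup|F_a - F_b|.  P-values
    are asymptotic: exp(-2 z^2) one-sided and the Kolmogorov distribution
    two-sided, with z = sqrt(nm/(n+m)) * D.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("ecdf_compare needs >= 2 values in each sample")
    if alternative not in ("two_sided", "greater", "less"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    diff = fa - fb
    d_plus = max(float(diff.max()), 0.0)
    d_minus = max(float(-diff.min()), 0.0)
    if alternative == "greater":
        d = d_plus
    elif alternative == "less":
        d = d_minus
    else:
        d = max(d_plus, d_minus)
    en = math.sqrt(len(a) * len(b) / (len(a) + len(b)))
    z = en * d
    if alternative == "two_sided":
        p = float(stats.kstwobign.sf(z)) if z > 0 else 1.0
    else:
        p = math.exp(-2.0 * z * z)
    return TestSummary(
        "ks_D", d, min(max(p, 0.0), 1.0), alternative,
        scaled_statistic=z, n=(len(a), len(b)),
    )


# ---------------------------------------------------------------------------
# convenience drivers used by the pipeline


def _per_cell_stat(table: pd.DataFrame, value_col: str) -> pd.Series:
    return table.groupby("cell_id")[value_col].mean()


def division_associations(
    delta_table: pd.DataFrame,
    range_table: pd.DataFrame,
    growth: GrowthTable,
) -> List[AssociationRecord]:
    """Correlations of delta (pooled and per hallmark) and of the per-modality
    range statistic with the nominal division rate; per-hallmark p-values get
    a BH q within the family."""
    records: List[AssociationRecord] = []
    df = _merge_delta_growth(delta_table, growth)
    records.append(
        correlate(df["delta"], df["division_rate"], "delta", "division_rate")
    )
    per_hallmark: List[AssociationRecord] = []
    for name, grp in df.groupby("set_name", sort=False):
        if len(grp) < 3:
            continue
        per_hallmark.append(
            correlate(grp["delta"], grp["division_rate"], "delta", "division_rate", hallmark=name)
        )
    records.extend(_bh_adjust(per_hallmark))
    for modality in ("mrna", "protein"):
        sub = range_table[range_table["modality"] == modality]
        merged = sub.merge(
            growth.division_rate.rename("division_rate"),
            left_on="cell_id", right_index=True, how="inner",
        )
        if len(merged) >= 3:
            records.append(
                correlate(
                    merged["range"], merged["division_rate"],
                    f"range_{modality}", "division_rate",
                )
            )
    return records


def inhibition_associations(
    delta_table: pd.DataFrame,
    range_table: pd.DataFrame,
    growth: GrowthTable,
) -> List[AssociationRecord]:
    """Correlations with per-(cell, drug) growth inhibition.  Cell-level task
    statistics are repeated across the drug panel (the pooled cloud of the
    scatter); missing inhibition values are dropped pairwise."""
    inh = growth.inhibition.stack(future_stack=True).rename("inhibition").reset_index()
    inh.columns = ["cell_id", "drug", "inhibition"]
    inh = inh[np.isfinite(inh["inhibition"])]
    records: List[AssociationRecord] = []

    df = delta_table.merge(inh, on="cell_id", how="inner")
    df = df[np.isfinite(df["delta"])]
    if len(df) >= 3:
        records.append(
            correlate(df["delta"], df["inhibition"], "delta", "growth_inhibition")
        )
        per_hallmark = []
        for name, grp in df.groupby("set_name", sort=False):
            if len(grp) >= 3:
                per_hallmark.append(
                    correlate(grp["delta"], grp["inhibition"], "delta",
                              "growth_inhibition", hallmark=name)
                )
        records.extend(_bh_adjust(per_hallmark))
    for modality in ("mrna", "protein"):
        sub = range_table[range_table["modality"] == modality]
        merged = sub.merge(inh, on="cell_id", how="inner")
        if len(merged) >= 3:
            records.append(
                correlate(merged["range"], merged["inhibition"],
                          f"range_{modality}", "growth_inhibition")
            )
    return records


def _bh_adjust(records: List[AssociationRecord]) -> List[AssociationRecord]:
    defined = [r for r in records if np.isfinite(r.p_value)]
    if not defined:
        return records
    q = multipletests([r.p_value for r in defined], method="fdr_bh")[1]
    qmap = {id(r): float(v) for r, v in zip(defined, q)}
    out = []
    for r in records:
        if id(r) in qmap:
            out.append(
                AssociationRecord(
                    r.predictor, r.response, r.pcc, r.p_value, r.n,
                    hallmark=r.hallmark, q_value=qmap[id(r)],
                    flagged=r.flagged, note=r.note,
                )
            )
        else:
            out.append(r)
    return out


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "predictor": r.predictor,
                "response": r.response,
                "hallmark": r.hallmark if r.hallmark is not None else "all",
                "pcc": r.pcc,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "n": r.n,
                "flagged": r.flagged,
            }
            for r in records
        ]
    )


def effects_to_frame(effects: Sequence[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": e.model,
                "hallmark": e.hallmark if e.hallmark is not None else "all",
                "estimate": e.estimate,
                "std_error": e.std_error,
                "p_value": e.p_value,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n": e.n,
            }
            for e in effects
        ]
    )


def plot_delta_division(
    delta_table: pd.DataFrame, growth: GrowthTable, path
) -> None:
    """Optional scatter of per-(cell, hallmark) delta vs division rate."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = _merge_delta_growth(delta_table, growth)
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, grp in df.groupby("set_name", sort=False):
        ax.scatter(grp["delta"], grp["division_rate"], s=12, alpha=0.6, label=name)
    ax.set_xlabel("enrichment delta (mRNA - protein NES)")
    ax.set_ylabel("division rate")
    ax.legend(fontsize=5, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
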