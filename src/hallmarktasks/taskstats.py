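"""The two bespoke decoupling statistics: enrichment delta and range.

Delta is the per-(cell, hallmark) difference between the mRNA-rank and the
protein-rank normalized enrichment scores; under the default sign convention
(``mrna_minus_protein``) a positive delta means a hallmark is transcribed
more strongly than it is translated.  The range statistic is, per cell and
modality, the spread between the most and least enriched hallmark - a proxy
for how concentrated the cell's resources are on few tasks.

Mean deltas are tested against a bootstrap null that pools the per-cell NES
of both modalities for one hallmark, draws two samples with replacement, and
records their difference of means.  Pooling the modalities is the
exchangeability null for "no modality effect".  The p-value carries an
add-one correction so it is never exactly zero at finite resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ParameterError

logger = logging.getLogger(__name__)

SIGN_CONVENTIONS = ("mrna_minus_protein", "protein_minus_mrna")


@dataclass
class TaskStatTable:
    """Tidy delta (cell_id, set_name, delta) and range (cell_id, modality,
    range) tables under one sign convention."""

    delta: pd.DataFrame
    range: pd.DataFrame
    sign_convention: str = "mrna_minus_protein"


@dataclass
class DifferenceTest:
    """Bootstrap test of one hallmark's mean enrichment delta (MD)."""

    set_name: str
    observed_md: float
    p_value: float
    n_boot: int
    sample_size: int
    seed: int
    null_draws: np.ndarray = field(repr=False, default=None)


def enrichment_delta(
    records_mrna: pd.DataFrame,
    records_protein: pd.DataFrame,
    sign_convention: str = "mrna_minus_protein",
) -> pd.DataFrame:
    """Signed NES difference per (cell, set); missing pairs are flagged."""
    if sign_convention not in SIGN_CONVENTIONS:
        raise ParameterError(f"sign_convention must be one of {SIGN_CONVENTIONS}")
    cols = ["cell_id", "set_name", "nes"]
    m = records_mrna[cols].rename(columns={"nes": "nes_mrna"})
    p = records_protein[cols].rename(columns={"nes": "nes_protein"})
    merged = m.merge(p, on=["cell_id", "set_name"], how="outer", indicator=True)
    missing = merged["_merge"] != "both"
    if missing.any():
        logger.warning("%d (cell, set) pair(s) missing from one modality", int(missing.sum()))
    merged = merged[~missing].drop(columns="_merge")
    if merged.empty:
        raise AnalysisError("no overlapping (cell, set) pairs between modalities")
    delta = merged["nes_mrna"] - merged["nes_protein"]
    if sign_convention == "protein_minus_mrna":
        delta = -delta
    out = merged[["cell_id", "set_name"]].copy()
    out["delta"] = delta.to_numpy()
    return out.reset_index(drop=True)


def enrichment_range(nes_values: Sequence[float]) -> float:
    """max NES - min NES over the hallmark sets of one ranked list."""
    vals = np.asarray(list(nes_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise AnalysisError("enrichment_range needs >= 1 defined NES value")
    return float(vals.max() - vals.min())


def range_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(cell, modality) range statistic from a combined records frame."""
    rows = []
    for (cell, modality), grp in records.groupby(["cell_id", "modality"], sort=False):
        rows.append((cell, modality, enrichment_range(grp["nes"])))
    return pd.DataFrame(rows, columns=["cell_id", "modality", "range"])


def compute_task_stats(
    records_mrna: pd.DataFrame,
    records_protein: pd.DataFrame,
    sign_convention: str = "mrna_minus_protein",
) -> TaskStatTable:
    delta = enrichment_delta(records_mrna, records_protein, sign_convention)
    combined = pd.concat([records_mrna, records_protein], ignore_index=True)
    return TaskStatTable(delta=delta, range=range_table(combined),
                         sign_convention=sign_convention)


def bootstrap_delta_test(
    scores_mrna: Sequence[float],
    scores_protein: Sequence[float],
    n_boot: int = 10_000,
    sample_size: Optional[int] = None,
    seed: int = 0,
    set_name: str = "",
) -> DifferenceTest:
    """Bootstrap null for the mean enrichment difference of one hallmark.

    Both modalities' per-cell scores are pooled; each resample draws two
    samples of ``sample_size`` (default: the number of cells) with
    replacement and records the difference of their means.  The p-value is
    (1 + #{|null| >= |observed MD|}) / (n_boot + 1).
    """
    a = np.asarray(list(scores_mrna), dtype=float)
    b = np.asarray(list(scores_protein), dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise AnalysisError("both score pools must be nonempty")
    if n_boot < 1000:
        raise ParameterError(f"n_boot must be >= 1000, got {n_boot}")
    if sample_size is None:
        sample_size = len(a)
    observed = float(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    if np.ptp(pool) == 0:
        # constant pool: a nonzero observed difference is impossible
        assert abs(observed) < 1e-12, "constant pool with nonzero observed MD"
        null = np.zeros(n_boot)
        return DifferenceTest(set_name, 0.0, 1.0, n_boot, sample_size, seed, null)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    idx = rng.integers(0, len(pool), size=(n_boot, 2, sample_size))
    draws = pool[idx].mean(axis=2)
    null = draws[:, 0] - draws[:, 1]
    p = (1 + int((np.abs(null) >= abs(observed)).sum())) / (n_boot + 1)
    return DifferenceTest(set_name, observed, float(p), n_boot, sample_size, seed, null)


def bootstrap_all_sets(
    records_mrna: pd.DataFrame,
    records_protein: pd.DataFrame,
    n_boot: int = 10_000,
    sample_size: Optional[int] = None,
    seed: int = 0,
    sign_convention: str = "mrna_minus_protein",
) -> List[DifferenceTest]:
    """One bootstrap difference test per hallmark, seeds derived per set."""
    if sign_convention not in SIGN_CONVENTIONS:
        raise ParameterError(f"sign_convention must be one of {SIGN_CONVENTIONS}")
    tests = []
    names = list(dict.fromkeys(records_mrna["set_name"]))
    for i, name in enumerate(names):
        m = records_mrna.loc[records_mrna["set_name"] == name]
        p = records_protein.loc[records_protein["set_name"] == name]
        m = m.set_index("cell_id")["nes"]
        p = p.set_index("cell_id")["nes"]
        cells = m.index.intersection(p.index)
        if len(cells) == 0:
            logger.warning("set %r has no paired cells; skipped", name)
            continue
        set_seed = int(np.random.SeedSequence([int(seed), 53, i]).generate_state(1)[0] % (2**31))
        first, second = (m[cells], p[cells])
        if sign_convention == "protein_minus_mrna":
            first, second = second, first
        tests.append(
            bootstrap_delta_test(first, second, n_boot, sample_size, set_seed, set_name=name)
        )
    return tests


def difference_tests_to_frame(tests: Sequence[DifferenceTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": t.set_name,
                "observed_md": t.observed_md,
                "p_value": t.p_value,
                "n_boot": t.n_boot,
                "sample_size": t.sample_size,
                "seed": t.seed,
            }
            for t in tests
        ]
    )
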