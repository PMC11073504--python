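"""Light-weight result containers for the hypothesis tests used across modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union


@dataclass(frozen=True)
class TestSummary:
    """Summary of a single hypothesis test.

    ``statistic_name`` is one of ``welch_t``, ``wilcoxon_W``, ``anova_F`` or
    ``ks_D``.  ``df`` is a float for the Welch t, a (between, within) pair for
    the ANOVA F, and ``None`` where the statistic has no degrees of freedom.
    For KS tests, ``scaled_statistic`` carries sqrt(n*m/(n+m)) * D, the
    sample-size-scaled variant some reports print alongside D in [0, 1].
    """

    statistic_name: str
    statistic: float
    p_value: float
    direction: str = "two_sided"  # greater | less | two_sided
    df: Union[float, Tuple[float, float], None] = None
    scaled_statistic: Optional[float] = None
    n: Optional[Tuple[int, int]] = None

    def to_dict(self) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "direction": self.direction,
        }
        if self.df is not None:
            d["df"] = list(self.df) if isinstance(self.df, tuple) else self.df
        if self.scaled_statistic is not None:
            d["scaled_statistic"] = self.scaled_statistic
        if self.n is not None:
            d["n"] = list(self.n)
        return d


@dataclass(frozen=True)
class AssociationRecord:
    """Pearson association of a task statistic with a growth phenotype."""

    predictor: str  # delta | range_mrna | range_protein
    response: str  # division_rate | growth_inhibition
    pcc: float
    p_value: float
    n: int
    hallmark: Optional[str] = None
    q_value: Optional[float] = None
    flagged: bool = False
    note: str = ""


@dataclass(frozen=True)
class EffectEstimate:
    """OLS slope of a growth response on a task statistic.

    ``model`` is ``pooled_fixed_effect`` for the hallmark-fixed-factor fit with
    a common slope, or ``per_hallmark`` for a separate simple regression.
    """

    estimate: float
    std_error: float
    p_value: float
    model: str
    n: int
    hallmark: Optional[str] = None
    ci_low: float = field(default=float("nan"))
    ci_high: float = field(default=float("nan"))
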