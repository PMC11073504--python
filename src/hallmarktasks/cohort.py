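"""Synthetic paired transcriptome/proteome cohorts with growth phenotypes.

The generator emulates the statistical structure the downstream analysis
assumes in a breast-cancer cell-line panel:

* log2 mRNA abundance per gene and cell is Gaussian around a gene baseline,
  with an additive transcription boost for genes in hallmark sets;
* log2 protein abundance is a linear transform of the mRNA signal plus
  Gaussian noise whose variance is calibrated so the expected same-cell
  (across-gene) Pearson correlation hits a per-gene coupling target, higher
  inside hallmark sets than outside;
* a configurable fraction of hallmark sets withhold their transcription boost
  from the protein side ("translation selectivity") - those sets are
  transcribed but not translated, the decoupling signal of interest;
* the nominal division rate is a linear function of each cell's mean true
  decoupling offset plus noise; drug growth inhibition is generated
  independently of the decoupling signal.

Abundances are exported on a nonnegative linear scale (2**log2), mimicking
RPKM-like inputs.  All randomness flows from one master seed; submodule
streams are derived with fixed offsets so reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import AbundanceMatrix, GeneSetCollection, GrowthTable, dump_json, load_json

# Published sizes of the ten curated cancer-hallmark gene lists, out of an
# assumed ~20k-gene genome; defaults scale these down to n_genes.
HALLMARK_BASE_SIZES = (1150, 649, 509, 610, 309, 1314, 1194, 710, 232, 462)
HALLMARK_NAMES = (
    "activating_invasion_and_metastasis",
    "tumor_promoting_inflammation",
    "inducing_angiogenesis",
    "evading_immune_destruction",
    "enabling_replicative_immortality",
    "sustaining_proliferative_signaling",
    "resisting_cell_death",
    "evading_growth_suppressors",
    "genome_instability_and_mutation",
    "reprogramming_energy_metabolism",
)
_GENOME_SIZE = 20_000


def _default_sizes(n_genes: int, n_hallmarks: int) -> List[int]:
    base = [HALLMARK_BASE_SIZES[i % len(HALLMARK_BASE_SIZES)] for i in range(n_hallmarks)]
    return [max(5, min(n_genes, round(b * n_genes / _GENOME_SIZE))) for b in base]


@dataclass
class CohortParams:
    """Study conditions for one synthetic cohort.

    Couplings are target same-cell Pearson correlations (unitless, in [0, 1]);
    ``transcription_offset`` is the mean log2 boost of hallmark genes on the
    mRNA side; ``translation_selectivity`` is the fraction of hallmark sets
    whose boost is NOT propagated to protein; ``division_slope`` is the linear
    effect of the per-cell mean decoupling offset on the division rate.
    """

    n_cells: int = 32
    n_genes: int = 3000
    n_hallmarks: int = 10
    hallmark_sizes: Optional[Sequence[int]] = None
    coupling_hallmark: float = 0.6
    coupling_background: float = 0.25
    transcription_offset: float = 0.5
    translation_selectivity: float = 0.5
    division_slope: float = -1.88
    division_intercept: float = 2.5
    division_noise_sd: float = 0.15
    n_drugs: int = 101
    seed: int = 0
    # secondary noise/scale knobs (log2 units unless stated)
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    gene_noise_sd_range: Tuple[float, float] = (0.4, 1.2)
    cell_boost_sd: float = 0.3  # between-cell spread of the hallmark boost
    set_boost_sd: float = 0.02  # extra per-(set, cell) jitter of the boost
    inhibition_mean: float = 0.5
    inhibition_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_hallmarks", "n_drugs"):
            if int(getattr(self, name)) < 1:
                raise ParameterError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("coupling_hallmark", "coupling_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.coupling_hallmark < self.coupling_background:
            raise ParameterError(
                "coupling_hallmark must be >= coupling_background "
                f"({self.coupling_hallmark} < {self.coupling_background})"
            )
        if not 0.0 <= self.translation_selectivity <= 1.0:
            raise ParameterError(
                f"translation_selectivity must be in [0, 1], got {self.translation_selectivity}"
            )
        if self.division_noise_sd < 0:
            raise ParameterError(f"division_noise_sd must be >= 0, got {self.division_noise_sd}")
        if self.hallmark_sizes is not None:
            sizes = list(self.hallmark_sizes)
            if len(sizes) != self.n_hallmarks:
                raise ParameterError(
                    f"hallmark_sizes must list {self.n_hallmarks} sizes, got {len(sizes)}"
                )
            for s in sizes:
                if not 1 <= s <= self.n_genes:
                    raise ParameterError(f"hallmark_sizes entries must be in [1, n_genes], got {s}")

    def resolved_sizes(self) -> List[int]:
        if self.hallmark_sizes is not None:
            return list(self.hallmark_sizes)
        return _default_sizes(self.n_genes, self.n_hallmarks)

    def set_names(self) -> List[str]:
        names = list(HALLMARK_NAMES[: self.n_hallmarks])
        for i in range(len(names), self.n_hallmarks):
            names.append(f"hallmark_{i + 1:02d}")
        return names


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort, for parameter-recovery tests."""

    seed: int
    coupling: pd.Series  # per-gene coupling target
    boosts: pd.DataFrame  # sets x cells transcription boosts (log2)
    withheld_sets: List[str]  # sets whose boost is not propagated to protein
    decoupling_proxy: pd.Series  # per-cell mean decoupling offset
    division_slope: float
    division_intercept: float
    division_noise_sd: float
    noise_variance: Dict[str, float] = field(default_factory=dict)

    def decoupling_table(self) -> pd.DataFrame:
        """Sets x cells true decoupling offsets: the boost for withheld sets,
        zero for sets whose boost reaches the protein side."""
        table = self.boosts.copy()
        propagated = [s for s in table.index if s not in set(self.withheld_sets)]
        table.loc[propagated] = 0.0
        return table

    def to_json(self, path) -> None:
        dump_json(
            {
                "seed": self.seed,
                "coupling": self.coupling.round(6).to_dict(),
                "boosts": {s: self.boosts.loc[s].round(6).to_dict() for s in self.boosts.index},
                "withheld_sets": list(self.withheld_sets),
                "decoupling_proxy": self.decoupling_proxy.round(6).to_dict(),
                "division_slope": self.division_slope,
                "division_intercept": self.division_intercept,
                "division_noise_sd": self.division_noise_sd,
                "noise_variance": self.noise_variance,
            },
            path,
        )

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = load_json(path)
        boosts = pd.DataFrame({s: pd.Series(v) for s, v in d["boosts"].items()}).T
        return cls(
            seed=d["seed"],
            coupling=pd.Series(d["coupling"]),
            boosts=boosts,
            withheld_sets=d["withheld_sets"],
            decoupling_proxy=pd.Series(d["decoupling_proxy"]),
            division_slope=d["division_slope"],
            division_intercept=d["division_intercept"],
            division_noise_sd=d["division_noise_sd"],
            noise_variance=d.get("noise_variance", {}),
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    # fixed-offset substreams from one master seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _solve_noise_variance(
    x: np.ndarray, x_prot: np.ndarray, rho: float
) -> float:
    """Per-class protein noise variance hitting a target same-cell Pearson r.

    ``x`` is the latent log2 mRNA of the class genes (genes x cells) and
    ``x_prot`` the protein-side predictor (mRNA minus withheld boosts).  The
    target correlation is across genes within a cell; moments are averaged
    over cells.  Solves r = cov(x, x_prot) / sqrt(var(x) (var(x_prot) + v)).
    """
    xc = x - x.mean(axis=0, keepdims=True)
    pc = x_prot - x_prot.mean(axis=0, keepdims=True)
    n = x.shape[0] - 1
    var_x = float((xc**2).sum(axis=0).mean() / n)
    var_p = float((pc**2).sum(axis=0).mean() / n)
    cov = float((xc * pc).sum(axis=0).mean() / n)
    if rho <= 0:
        return 1e4  # effectively uncoupled; bounded so 2**y stays finite
    v = cov**2 / (rho**2 * var_x) - var_p
    return min(max(v, 0.0), 1e4)


def generate_cohort(
    params: CohortParams,
) -> Tuple[AbundanceMatrix, AbundanceMatrix, GeneSetCollection, GrowthTable, SyntheticTruth]:
    """Generate one cohort under ``params``; deterministic given the seed."""
    p = params
    genes = [f"G{i + 1:05d}" for i in range(p.n_genes)]
    cells = [f"CELL{i + 1:02d}" for i in range(p.n_cells)]
    names = p.set_names()
    sizes = p.resolved_sizes()

    rng_genes = _rng(p.seed, 1)
    rng_sets = _rng(p.seed, 2)
    rng_mrna = _rng(p.seed, 3)
    rng_protein = _rng(p.seed, 4)
    rng_growth = _rng(p.seed, 5)

    mu = rng_genes.normal(p.baseline_mean, p.baseline_sd, size=p.n_genes)
    lo, hi = p.gene_noise_sd_range
    sigma = rng_genes.uniform(lo, hi, size=p.n_genes)

    # hallmark sets sampled independently from the universe (overlap allowed)
    membership = np.zeros((p.n_genes, p.n_hallmarks), dtype=bool)
    sets: Dict[str, List[str]] = {}
    for j, (name, size) in enumerate(zip(names, sizes)):
        idx = rng_sets.choice(p.n_genes, size=size, replace=False)
        idx.sort()
        membership[idx, j] = True
        sets[name] = [genes[i] for i in idx]
    collection = GeneSetCollection(universe=list(genes), sets=sets)

    n_withheld = round(p.translation_selectivity * p.n_hallmarks)
    withheld_idx = np.sort(rng_sets.choice(p.n_hallmarks, size=n_withheld, replace=False))
    withheld = [names[i] for i in withheld_idx]

    # transcription boosts: a per-cell investment level shared by the
    # hallmark sets of that cell, plus small per-(set, cell) jitter
    cell_level = rng_mrna.normal(p.transcription_offset, p.cell_boost_sd, size=p.n_cells)
    boosts = cell_level[None, :] + rng_mrna.normal(
        0.0, p.set_boost_sd, size=(p.n_hallmarks, p.n_cells)
    )

    z = rng_mrna.normal(size=(p.n_genes, p.n_cells))
    x = mu[:, None] + sigma[:, None] * z + membership.astype(float) @ boosts

    withheld_mask = np.zeros(p.n_hallmarks, dtype=bool)
    withheld_mask[withheld_idx] = True
    withheld_part = membership[:, withheld_mask].astype(float) @ boosts[withheld_mask]
    x_prot = x - withheld_part

    in_hallmark = membership.any(axis=1)
    coupling = np.where(in_hallmark, p.coupling_hallmark, p.coupling_background)
    noise_var = {}
    y = np.empty_like(x)
    for label, mask, rho in (
        ("hallmark", in_hallmark, p.coupling_hallmark),
        ("background", ~in_hallmark, p.coupling_background),
    ):
        if mask.sum() < 3:
            v = 0.0
        else:
            v = _solve_noise_variance(x[mask], x_prot[mask], rho)
        noise_var[label] = v
        y[mask] = x_prot[mask] + np.sqrt(v) * rng_protein.normal(size=(int(mask.sum()), p.n_cells))

    mrna = AbundanceMatrix("mrna", pd.DataFrame(2.0**x, index=genes, columns=cells))
    protein = AbundanceMatrix("protein", pd.DataFrame(2.0**y, index=genes, columns=cells))

    proxy = boosts[withheld_mask].mean(axis=0) if n_withheld else np.zeros(p.n_cells)
    division = (
        p.division_intercept
        + p.division_slope * proxy
        + rng_growth.normal(0.0, p.division_noise_sd, size=p.n_cells)
    )
    drugs = [f"DRUG{i + 1:03d}" for i in range(p.n_drugs)]
    inhibition = rng_growth.normal(p.inhibition_mean, p.inhibition_sd, size=(p.n_cells, p.n_drugs))
    growth = GrowthTable(
        division_rate=pd.Series(division, index=cells, name="division_rate"),
        inhibition=pd.DataFrame(inhibition, index=cells, columns=drugs),
    )

    truth = SyntheticTruth(
        seed=p.seed,
        coupling=pd.Series(coupling, index=genes, name="coupling"),
        boosts=pd.DataFrame(boosts, index=names, columns=cells),
        withheld_sets=withheld,
        decoupling_proxy=pd.Series(proxy, index=cells, name="decoupling_proxy"),
        division_slope=p.division_slope,
        division_intercept=p.division_intercept,
        division_noise_sd=p.division_noise_sd,
        noise_variance=noise_var,
    )
    return mrna, protein, collection, growth, truth
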