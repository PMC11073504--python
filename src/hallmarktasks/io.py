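"""Readers and writers for the three plain-text input formats.

Abundance matrices are tab-separated with a ``gene_id`` first column and one
column per cell line.  Gene sets use the MSigDB GMT convention (set name,
description, tab-separated members).  The growth table is tab-separated with
``cell_id``, ``division_rate`` and one column per drug; blank inhibition cells
are preserved as missing, never imputed.

Gene identifiers are matched across modalities by exact string equality after
whitespace trimming; no symbol/alias resolution is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

MODALITIES = ("mrna", "protein")


@dataclass
class AbundanceMatrix:
    """Genes x cells nonnegative abundances for one modality.

    ``data`` is a DataFrame indexed by gene ID with cell-ID columns; values
    are RPKM-like (mRNA) or MS-intensity-like (protein), unitless.
    """

    modality: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise FormatError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate cell IDs in abundance matrix")
        if self.data.shape[0] < 3 or self.data.shape[1] < 1:
            raise FormatError(
                f"abundance matrix needs >= 3 genes and >= 1 cell, got {self.data.shape}"
            )
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise FormatError("abundance matrix contains non-finite values")
        if (values < 0).any():
            g, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative abundance for gene {self.data.index[g]!r} "
                f"in cell {self.data.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def cell_ids(self) -> List[str]:
        return list(self.data.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets over a gene universe; member lists are deduplicated."""

    universe: List[str]
    sets: Dict[str, List[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members after parsing")

    @property
    def names(self) -> List[str]:
        return list(self.sets)

    def sizes(self) -> Dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}


@dataclass
class GrowthTable:
    """Per-cell nominal division rate plus a cells x drugs inhibition matrix.

    Missing inhibition entries stay NaN (flagged, not imputed).
    """

    division_rate: pd.Series  # indexed by cell_id
    inhibition: pd.DataFrame  # cells x drugs, may contain NaN

    def __post_init__(self) -> None:
        if self.division_rate.index.has_duplicates:
            raise FormatError("duplicate cell IDs in growth table")
        if not np.isfinite(self.division_rate.to_numpy()).all():
            raise FormatError("division_rate contains missing or non-numeric values")
        if not self.inhibition.index.equals(self.division_rate.index):
            self.inhibition = self.inhibition.reindex(self.division_rate.index)

    @property
    def cell_ids(self) -> List[str]:
        return list(self.division_rate.index)


# ---------------------------------------------------------------------------
# abundance matrices


def read_abundance(path: str | Path, modality: str) -> AbundanceMatrix:
    """Read a TSV abundance matrix; genes with any non-numeric entry are dropped
    with a logged count, negatives and duplicate IDs raise :class:`FormatError`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty abundance matrix in {path}")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene IDs in {path}: {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.warning(
            "%s: dropped %d gene(s) with non-numeric entries", path.name, int(bad.sum())
        )
        numeric = numeric.loc[~bad]
    values = numeric.to_numpy()
    if (values < 0).any():
        g, c = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative value for gene {numeric.index[g]!r} in cell "
            f"{numeric.columns[c]!r}"
        )
    return AbundanceMatrix(modality=modality, data=numeric)


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write TSV with 2-decimal rounding (RPKM-like precision)."""
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.2f")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path, universe: Optional[Sequence[str]] = None) -> GeneSetCollection:
    """Parse a GMT file.  Duplicate members within a line are deduplicated with
    a warning; duplicate set names and member-less lines are format errors.
    The universe defaults to the union of all members."""
    path = Path(path)
    sets: Dict[str, List[str]] = {}
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has no members")
            name, _description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: GMT line has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning(
                    "%s: set %r listed %d duplicate member(s); deduplicated",
                    path.name, name, len(members) - len(deduped),
                )
            sets[name] = deduped
    if n_lines == 0:
        logger.warning("%s: GMT file is empty; returning an empty collection", path.name)
    if universe is None:
        seen: Dict[str, None] = {}
        for members in sets.values():
            for m in members:
                seen.setdefault(m)
        universe = list(seen)
    return GeneSetCollection(universe=list(universe), sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# growth table


def read_growth(path: str | Path) -> GrowthTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    if "division_rate" not in df.columns:
        raise FormatError(f"{path}: missing required column 'division_rate'")
    rates = pd.to_numeric(df["division_rate"], errors="coerce")
    if rates.isna().any():
        bad = df.index[rates.isna()].tolist()
        raise FormatError(f"{path}: non-numeric division_rate for cell(s) {bad[:5]}")
    inhibition = df.drop(columns=["division_rate"]).apply(pd.to_numeric, errors="coerce")
    return GrowthTable(division_rate=rates.astype(float), inhibition=inhibition)


def write_growth(table: GrowthTable, path: str | Path) -> None:
    df = pd.concat([table.division_rate.rename("division_rate"), table.inhibition], axis=1)
    df.to_csv(path, sep="\t", index_label="cell_id", float_format="%.4f")


# ---------------------------------------------------------------------------
# cross-modality gene matching


def shared_genes(mrna: AbundanceMatrix, protein: AbundanceMatrix) -> List[str]:
    """Genes present in both modalities, in mRNA order; drops are logged."""
    protein_set = set(protein.gene_ids)
    shared = [g for g in mrna.gene_ids if g in protein_set]
    dropped = len(mrna.gene_ids) + len(protein.gene_ids) - 2 * len(shared)
    if dropped:
        logger.info("dropped %d gene(s) absent from one modality", dropped)
    return shared


# ---------------------------------------------------------------------------
# small JSON helper used by the cohort truth and pipeline report


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        v = float(value)
        return None if not np.isfinite(v) else v
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.bool_,)):
        return bool(value)
    raise TypeError(f"not JSON serializable: {type(value)}")


def dump_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def load_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
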