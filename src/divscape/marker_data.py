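"""Reading, validation and filtering of dominant-marker presence/absence matrices.

The canonical data model is :class:`MarkerMatrix`: one matrix per species,
individuals as rows, band loci as columns, values 0/1 with NaN for missing,
and a population label per individual. Populations are never merged across
species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DatasetBelowThresholdError, ParseError

logger = logging.getLogger(__name__)

#: Default tokens interpreted as missing data.
DEFAULT_MISSING_TOKENS = ("NA", "")

_PRESENT_TOKENS = {"1"}
_ABSENT_TOKENS = {"0"}


@dataclass
class MarkerMatrix:
    """Binary individuals x loci band matrix with a population assignment.

    Values are stored as a float array where 1.0 = band present, 0.0 = band
    absent and NaN = missing. Row order (individuals) and column order (loci)
    are preserved exactly as read.
    """

    individuals: list[str]
    loci: list[str]
    values: np.ndarray
    populations: list[str]
    species: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.individuals), len(self.loci)
        if n < 1 or m < 1:
            raise ValueError("MarkerMatrix needs at least 1 individual and 1 locus")
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} individuals x {m} loci"
            )
        if len(self.populations) != n:
            raise ValueError("one population label required per individual")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual identifiers")
        if len(set(self.loci)) != m:
            raise ValueError("duplicate locus identifiers")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.values) | (self.values == 0.0) | (self.values == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary value {self.values[i, j]!r} at individual "
                f"{self.individuals[i]!r}, locus {self.loci[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_ids(self) -> list[str]:
        """Population identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    @property
    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.populations:
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def population_of(self, individual: str) -> str:
        return self.populations[self.individuals.index(individual)]

    def to_frame(self) -> pd.DataFrame:
        """Round-trippable frame: individual_id, population_id, [species], loci."""
        df = pd.DataFrame(self.values, columns=self.loci)
        df.insert(0, "population_id", self.populations)
        df.insert(0, "individual_id", self.individuals)
        if self.species is not None:
            df.insert(2, "species", self.species)
        return df


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_marker_matrix(
    path: str | Path,
    *,
    delimiter: str | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    individual_col: str = "individual_id",
    population_col: str = "population_id",
    species_col: str = "species",
    species: str | None = None,
) -> MarkerMatrix:
    """Read a delimited presence/absence matrix into a :class:`MarkerMatrix`.

    The header row names the loci; each subsequent row is one individual with
    an individual-ID column and a population-ID column (an optional species
    column is honoured). Any token not in ``{"0", "1"}`` and not declared in
    ``missing_tokens`` raises :class:`ParseError` naming the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (individual_col, population_col):
        if col not in raw.columns:
            raise ParseError(f"{path.name}: required column {col!r} not found")
    individuals = raw[individual_col].tolist()
    if len(set(individuals)) != len(individuals):
        dup = raw[individual_col][raw[individual_col].duplicated()].iloc[0]
        raise ParseError(f"{path.name}: duplicate individual ID {dup!r}")
    populations = raw[population_col].tolist()
    if species is None and species_col in raw.columns:
        uniq = raw[species_col].unique()
        if len(uniq) > 1:
            raise ParseError(
                f"{path.name}: multiple species in one matrix: {sorted(uniq)}"
            )
        species = uniq[0]
    locus_cols = [
        c for c in raw.columns if c not in {individual_col, population_col, species_col}
    ]
    if not locus_cols:
        raise ParseError(f"{path.name}: no locus columns found")
    missing = set(missing_tokens)
    values = np.empty((len(individuals), len(locus_cols)), dtype=float)
    for j, col in enumerate(locus_cols):
        tokens = raw[col].str.strip()
        col_vals = np.full(len(tokens), np.nan)
        present = tokens.isin(_PRESENT_TOKENS)
        absent = tokens.isin(_ABSENT_TOKENS)
        is_missing = tokens.isin(missing)
        bad = ~(present | absent | is_missing)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path.name}: unexpected token {tokens.iloc[i]!r} at row "
                f"{individuals[i]!r}, column {col!r} (declare it as missing?)"
            )
        col_vals[present.to_numpy()] = 1.0
        col_vals[absent.to_numpy()] = 0.0
        values[:, j] = col_vals
    return MarkerMatrix(
        individuals=individuals,
        loci=locus_cols,
        values=values,
        populations=populations,
        species=species,
    )


def write_marker_matrix(m: MarkerMatrix, path: str | Path) -> None:
    """Write in the same delimited layout :func:`read_marker_matrix` consumes."""
    path = Path(path)
    sep = _detect_delimiter(path, None)
    df = m.to_frame()
    locus_part = df[m.loci].astype(object)
    locus_part = locus_part.where(~locus_part.isna(), "NA")
    locus_part = locus_part.map(lambda v: v if v == "NA" else str(int(v)))
    df[m.loci] = locus_part
    df.to_csv(path, sep=sep, index=False)


def filter_dataset(
    m: MarkerMatrix,
    min_individuals: int = 5,
    min_populations: int = 5,
) -> MarkerMatrix:
    """Apply the dataset inclusion rule.

    Populations with fewer than ``min_individuals`` individuals are dropped
    (with a warning); if fewer than ``min_populations`` populations survive,
    the dataset is rejected with :class:`DatasetBelowThresholdError`.
    Idempotent.
    """
    sizes = m.population_sizes
    keep_pops = {p for p, n in sizes.items() if n >= min_individuals}
    for p in m.population_ids:
        if p not in keep_pops:
            logger.warning(
                "dropping population %r (%d < %d individuals)%s",
                p, sizes[p], min_individuals,
                f" [species {m.species}]" if m.species else "",
            )
    if len(keep_pops) < min_populations:
        raise DatasetBelowThresholdError(
            f"dataset below inclusion threshold: {len(keep_pops)} populations "
            f"with >= {min_individuals} individuals (need >= {min_populations})"
            + (f" [species {m.species}]" if m.species else "")
        )
    if len(keep_pops) == len(sizes):
        return m
    mask = [p in keep_pops for p in m.populations]
    idx = np.flatnonzero(mask)
    return MarkerMatrix(
        individuals=[m.individuals[i] for i in idx],
        loci=list(m.loci),
        values=m.values[idx],
        populations=[m.populations[i] for i in idx],
        species=m.species,
    )


def split_by_population(m: MarkerMatrix) -> dict[str, MarkerMatrix]:
    """Partition by population, preserving individual and locus order."""
    out: dict[str, MarkerMatrix] = {}
    pops = np.asarray(m.populations)
    for pop in m.population_ids:
        idx = np.flatnonzero(pops == pop)
        out[pop] = MarkerMatrix(
            individuals=[m.individuals[i] for i in idx],
            loci=list(m.loci),
            values=m.values[idx],
            populations=[pop] * len(idx),
            species=m.species,
        )
    return out


def concat_populations(parts: Mapping[str, MarkerMatrix]) -> MarkerMatrix:
    """Inverse of :func:`split_by_population` (up to population-block order)."""
    mats = list(parts.values())
    loci = mats[0].loci
    for sub in mats[1:]:
        if sub.loci != loci:
            raise ValueError("sub-matrices disagree on locus order")
    return MarkerMatrix(
        individuals=[i for sub in mats for i in sub.individuals],
        loci=list(loci),
        values=np.vstack([sub.values for sub in mats]),
        populations=[p for sub in mats for p in sub.populations],
        species=mats[0].species,
    )
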