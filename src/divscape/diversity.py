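"""Per-population gene diversity and genetic rarity for dominant markers.

Band presence/absence is treated as a two-state character. Gene diversity per
locus uses the small-sample-corrected pairwise-difference form

    h_j = n_j / (n_j - 1) * 2 * p_j * (1 - p_j)

where p_j is the band-presence frequency and n_j the number of non-missing
individuals at locus j in the population; for binary data this is identical
to the proportion of differing pairs among all individual pairs, which gives
an exact brute-force oracle. No Hardy-Weinberg (square-root) transform of
band frequencies is applied.

Genetic rarity of a target population is the mean, over the bands the target
carries, of 1 / (number of populations in the species dataset carrying that
band). It is computed within species only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import EmptyBandSetError, InsufficientSampleError
from .marker_data import MarkerMatrix, split_by_population

logger = logging.getLogger(__name__)


def band_frequencies(sub: MarkerMatrix) -> pd.DataFrame:
    """Per-locus band-presence frequency within one population sub-matrix.

    Returns a frame with columns ``locus``, ``p`` (NaN when undefined) and
    ``n`` (count of non-missing individuals at the locus).
    """
    vals = sub.values
    n = np.sum(~np.isnan(vals), axis=0)
    present = np.nansum(vals, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, present / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"locus": sub.loci, "p": p, "n": n.astype(int)})


def _hs_components(sub: MarkerMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus h_j values and the usable-locus mask (n_j >= 2)."""
    freq = band_frequencies(sub)
    n = freq["n"].to_numpy(dtype=float)
    p = freq["p"].to_numpy(dtype=float)
    usable = n >= 2
    h = np.zeros_like(p)
    nz = usable
    h[nz] = n[nz] / (n[nz] - 1.0) * 2.0 * p[nz] * (1.0 - p[nz])
    return h, usable


def gene_diversity_hs(sub: MarkerMatrix) -> float:
    """Average gene diversity per locus H_S for one population.

    Loci with fewer than 2 non-missing individuals are excluded. Raises
    :class:`InsufficientSampleError` when no locus qualifies. The result is
    clamped to [0, 1].
    """
    h, usable = _hs_components(sub)
    if not usable.any():
        raise InsufficientSampleError(
            "no locus with >= 2 non-missing individuals"
        )
    return float(np.clip(np.mean(h[usable]), 0.0, 1.0))


def n_loci_used(sub: MarkerMatrix) -> int:
    _, usable = _hs_components(sub)
    return int(usable.sum())


def _presence_by_population(m: MarkerMatrix) -> pd.DataFrame:
    """Population x locus boolean table: band present in >= 1 individual."""
    rows = {}
    for pop, sub in split_by_population(m).items():
        with np.errstate(invalid="ignore"):
            rows[pop] = np.nansum(sub.values, axis=0) > 0
    return pd.DataFrame.from_dict(rows, orient="index", columns=m.loci)


def _rarity_from_presence(presence: pd.DataFrame, target: str) -> float:
    carried = presence.loc[target].to_numpy()
    if not carried.any():
        raise EmptyBandSetError(f"population {target!r} carries no bands")
    d = presence.to_numpy().sum(axis=0)[carried]
    return float(np.mean(1.0 / d))


def genetic_rarity(m: MarkerMatrix, target: str) -> float:
    """Frequency-down-weighted rarity of ``target`` within its species dataset.

    For each band the target carries, D_a = number of populations of ``m``
    carrying the band (D_a >= 1 by construction); rarity is the mean of
    1 / D_a over those bands. Bounded by 1/P and 1.
    """
    if target not in m.population_ids:
        raise KeyError(f"unknown population {target!r}")
    return _rarity_from_presence(_presence_by_population(m), target)


def diversity_table(m: MarkerMatrix) -> pd.DataFrame:
    """Assemble the per-population diversity table for one species dataset.

    Columns: species, population_id, n_individuals, n_loci_used, Hs, rarity.
    Populations where a statistic is undefined get NaN there (logged), so the
    table always has one row per population. Deterministic given ``m``.
    """
    rows = []
    presence = _presence_by_population(m)
    for pop, sub in split_by_population(m).items():
        try:
            hs = gene_diversity_hs(sub)
            used = n_loci_used(sub)
        except InsufficientSampleError as exc:
            logger.warning("population %r: %s", pop, exc)
            hs, used = np.nan, 0
        try:
            rar = _rarity_from_presence(presence, pop)
        except EmptyBandSetError as exc:
            logger.warning("population %r: %s", pop, exc)
            rar = np.nan
        rows.append(
            {
                "species": m.species,
                "population_id": pop,
                "n_individuals": sub.n_individuals,
                "n_loci_used": used,
                "Hs": hs,
                "rarity": rar,
            }
        )
    return pd.DataFrame(rows)


def pairwise_mismatch_hs(sub: MarkerMatrix) -> float:
    """Independent oracle: mean over loci of the proportion of differing pairs.

    Exhaustively enumerates all individual pairs per locus (complete data
    only). Used to cross-check :func:`gene_diversity_hs`; intentionally slow.
    """
    vals = sub.values
    if np.isnan(vals).any():
        raise ValueError("oracle requires complete data")
    n = vals.shape[0]
    per_locus = []
    for j in range(vals.shape[1]):
        diff = 0
        for a in range(n):
            for b in range(a + 1, n):
                diff += int(vals[a, j] != vals[b, j])
        per_locus.append(diff / (n * (n - 1) / 2))
    return float(np.mean(per_locus))
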