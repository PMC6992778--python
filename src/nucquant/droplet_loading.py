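"""Poisson statistics of droplet co-encapsulation.

Cells suspended at concentration ``c`` (per mL) encapsulated into droplets
of volume ``V`` (pL) are loaded with Poisson rate lambda = c x V x 1e-9.
At the dilute loadings used in droplet RNA-seq (e.g. 200,000 cells/mL in
~380 pL droplets, lambda ~ 0.076) most droplets are empty and the doublet
fraction among occupied droplets,

    (1 - e^-lam - lam e^-lam) / (1 - e^-lam),

stays in the low percent range. A two-species (barnyard) mixing experiment
estimates the realized doublet rate empirically: cross-species barcodes
are observed collisions, and the total doublet rate follows after
correcting for the fraction 2f(1-f) of doublets that mix species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LoadingParameters",
    "BarnyardCounts",
    "loading_lambda",
    "droplets_per_ml",
    "occupancy_pmf",
    "doublet_fraction",
    "simulate_loading",
    "species_mixing_doublets",
]

ML_PER_PL = 1e-9


@dataclass(frozen=True)
class LoadingParameters:
    concentration: float  # particles per mL
    droplet_volume: float  # pL

    def __post_init__(self) -> None:
        if self.concentration < 0 or self.droplet_volume < 0:
            raise ValueError("concentration and droplet volume must be >= 0")

    @property
    def lam(self) -> float:
        return loading_lambda(self.concentration, self.droplet_volume)


def loading_lambda(concentration: float, droplet_volume: float) -> float:
    """Expected particles per droplet: concentration[mL^-1] x volume[pL] x 1e-9."""
    if concentration < 0 or droplet_volume < 0:
        raise ValueError("inputs must be non-negative")
    return concentration * droplet_volume * ML_PER_PL


def droplets_per_ml(droplet_volume: float) -> tuple[float, float]:
    """Droplets per mL of emulsion: 1e9 / volume[pL].

    Returns (raw, rounded to 2 significant figures)."""
    if droplet_volume <= 0:
        raise ValueError("droplet volume must be positive")
    raw = 1e9 / droplet_volume
    exponent = np.floor(np.log10(raw))
    rounded = round(raw / 10**exponent, 1) * 10**exponent
    return raw, float(rounded)


def occupancy_pmf(lam: float, k_max: int = 5) -> np.ndarray:
    """Poisson occupancy probabilities for k = 0..k_max plus the tail
    P(k > k_max) as the final entry; sums to 1."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    ks = np.arange(k_max + 1)
    pmf = stats.poisson.pmf(ks, lam)
    tail = stats.poisson.sf(k_max, lam)
    return np.append(pmf, tail)


def doublet_fraction(lam: float) -> float:
    """Fraction of *occupied* droplets holding >= 2 particles."""
    if lam <= 0:
        raise ValueError("lambda must be positive (undefined for empty loading)")
    # -expm1(-lam) = 1 - e^-lam, stable for small lam
    occupied = -np.expm1(-lam)
    return float((occupied - lam * np.exp(-lam)) / occupied)


def simulate_loading(lam: float, n_droplets: int, seed: int | np.random.Generator):
    """Draw droplet occupancies; returns (occupancy tallies as a Counter-like
    dict, empirical doublet fraction among occupied droplets)."""
    if n_droplets < 1:
        raise ValueError("need at least one droplet")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occ = rng.poisson(lam, size=n_droplets)
    values, counts = np.unique(occ, return_counts=True)
    tallies = dict(zip(values.tolist(), counts.tolist()))
    occupied = int((occ >= 1).sum())
    doublets = int((occ >= 2).sum())
    frac = doublets / occupied if occupied else float("nan")
    return tallies, frac


@dataclass
class BarnyardCounts:
    """Per-barcode read counts attributed to each of two species."""

    counts: pd.DataFrame  # columns = two species labels, index = barcodes
    purity_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.counts.shape[1] != 2:
            raise ValueError("barnyard counts need exactly two species columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not 0.5 < self.purity_threshold <= 1:
            raise ValueError("purity threshold must be in (0.5, 1]")


def species_mixing_doublets(
    counts: BarnyardCounts, mixing_fraction: float
) -> dict[str, float]:
    """Estimate the doublet rate from a two-species mixing run.

    A barcode is a cross-species collision when its minor-species read
    fraction exceeds ``1 - purity_threshold``. Only a fraction
    ``2f(1-f)`` of true doublets mixes species, so the inferred total
    doublet rate is observed / (2f(1-f)), capped at 1. Symmetric under
    swapping the species labels.
    """
    if not 0 < mixing_fraction < 1:
        raise ValueError("mixing fraction must be in (0, 1)")
    df = counts.counts
    totals = df.sum(axis=1)
    informative = totals > 0
    if not informative.any():
        raise ValueError("no barcodes with reads")
    if (df.loc[informative] > 0).any(axis=0).sum() < 2:
        raise ValueError("single-species input: both species must be present")
    minor = df.loc[informative].min(axis=1) / totals[informative]
    collisions = minor > (1 - counts.purity_threshold)
    observed = float(collisions.mean())
    f = mixing_fraction
    inferred = min(1.0, observed / (2 * f * (1 - f)))
    return {
        "n_barcodes": int(informative.sum()),
        "observed_collision_rate": observed,
        "inferred_doublet_rate": inferred,
    }
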