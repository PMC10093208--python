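"""Extracellular-vesicle arithmetic: size classes, tau fractions, uptake.

Small helpers around nanoparticle-tracking (NTA) size data and ELISA tau
quantities: percentage of particles in the exosome-like (10–150 nm) vs
ectosome-like (> 150 nm) size class, the distribution of tau across the
free-form / small-EV / large-EV secretion fractions, and the uptake
efficiency

    % uptake = quantity of tau in astrocytes x 100 / quantity of tau added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import ParticleSample

__all__ = [
    "SizePartition",
    "UptakeResult",
    "fraction_distribution",
    "partition_sizes",
    "read_diameter_csv",
    "uptake_efficiency",
]


@dataclass(frozen=True)
class SizePartition:
    """Percentage split of a particle sample at the small/large boundary.

    Percentages are over particles above ``lower_cut``; a diameter exactly at
    the boundary falls in the small class.  ``pct_small + pct_large = 100``
    exactly (before any rounding).
    """

    pct_small: float
    pct_large: float
    n_below_cut: int
    n_included: int
    boundary_nm: float = 150.0
    lower_cut_nm: float = 10.0


def partition_sizes(
    sample: ParticleSample,
    boundary: float = 150.0,
    lower_cut: float = 10.0,
    weights: Sequence[float] | None = None,
) -> SizePartition:
    """Split particle diameters into <=150 nm and >150 nm classes.

    ``weights`` (e.g. per-bin concentrations from a binned NTA export) weight
    each diameter; by default every particle counts once.
    """
    d = np.asarray(sample.diameters, float)
    if d.size == 0:
        raise ValueError("empty particle sample")
    if boundary <= lower_cut:
        raise ValueError("boundary must exceed lower_cut")
    w = np.ones_like(d) if weights is None else np.asarray(weights, float)
    if w.shape != d.shape:
        raise ValueError("weights must match diameters")
    if (w < 0).any():
        raise ValueError("weights must be >= 0")
    keep = d > lower_cut
    if not keep.any() or w[keep].sum() == 0:
        raise ValueError("no particles above the lower size cut")
    total = w[keep].sum()
    small = w[keep & (d <= boundary)].sum()
    pct_small = 100.0 * small / total
    return SizePartition(
        pct_small=float(pct_small),
        pct_large=float(100.0 - pct_small),
        n_below_cut=int((~keep).sum()),
        n_included=int(keep.sum()),
        boundary_nm=boundary,
        lower_cut_nm=lower_cut,
    )


def fraction_distribution(quantities: Mapping[str, float]) -> pd.Series:
    """Percentage of total tau in each secretion fraction (FFP/SEV/LEV...).

    Scale-invariant: multiplying every quantity by c > 0 leaves the
    percentages unchanged; they sum to 100 exactly.
    """
    s = pd.Series(quantities, dtype=float)
    if (s < 0).any():
        raise ValueError("quantities must be >= 0")
    total = s.sum()
    if total <= 0:
        raise ValueError("total quantity must be > 0")
    return s * 100.0 / total


@dataclass(frozen=True)
class UptakeResult:
    tau_in_astrocytes: float
    tau_added: float
    pct_uptake: float
    inconsistent: bool  # uptake above 100% flags inconsistent inputs


def uptake_efficiency(tau_in_astrocytes: float, tau_added: float) -> UptakeResult:
    """Tau uptake efficiency: quantity in astrocytes x 100 / quantity added."""
    if tau_added <= 0:
        raise ValueError("tau_added must be > 0")
    if tau_in_astrocytes < 0:
        raise ValueError("tau_in_astrocytes must be >= 0")
    pct = tau_in_astrocytes * 100.0 / tau_added
    return UptakeResult(tau_in_astrocytes, tau_added, pct, pct > 100.0)


def read_diameter_csv(path, column: str = "diameter_nm", label: str = "") -> ParticleSample:
    """Read an NTA-style one-diameter-per-row CSV into a ParticleSample."""
    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"column {column!r} not in {sorted(df.columns)}")
    return ParticleSample(df[column].to_numpy(float), label=label)
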