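"""Delta notation, standard normalization, species summaries and trophic transfers.

Isotope abundances are expressed as deltas in per mil:

    delta = ((R_sample - R_standard) / R_standard) * 1000

where R is the heavy/light isotope ratio (13C/12C against V-PDB, 15N/14N
against atmospheric N2).  Mass-spectrometer linearity errors are corrected by
a two-point normalization: the unique line mapping the measured values of two
in-house standards onto their known values, fitted per isotope and applied to
all sample deltas.  Community trophic structure is then read off the d15N
axis: a fixed per-transfer enrichment (2.5 per mil by default) converts a
d15N difference into a number of trophic transfers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import IsotopeMeasurement, RatioPair
from .errors import AnalysisError, ValidationError

__all__ = [
    "delta_from_ratios",
    "NormalizationModel",
    "fit_two_point_normalization",
    "SpeciesIsotopeSummary",
    "CommunitySummary",
    "summarize_species",
    "trophic_transfers",
    "apply_preservation_offset",
]


def delta_from_ratios(pair: RatioPair) -> float:
    """Per-mil delta of a sample ratio relative to its standard ratio."""
    return (pair.r_sample - pair.r_standard) / pair.r_standard * 1000.0


@dataclass(frozen=True)
class NormalizationModel:
    """The line ``known = slope * measured + intercept`` fitted through two
    standards; applying it to the measured standard values returns the known
    values exactly (two-point interpolation)."""

    slope: float
    intercept: float
    known: tuple[float, float]
    measured: tuple[float, float]

    def apply(self, values):
        return self.slope * np.asarray(values, dtype=float) + self.intercept


def fit_two_point_normalization(
    known: Sequence[float], measured: Sequence[float]
) -> NormalizationModel:
    """Fit the unique line mapping two measured standard deltas onto their
    known values.  Raises if the measured standards coincide (degenerate fit)
    or the known standards coincide (no information)."""
    (k1, k2), (m1, m2) = known, measured
    if m1 == m2:
        raise AnalysisError("measured standard values are identical; fit is degenerate")
    if k1 == k2:
        raise AnalysisError("known standard values must differ")
    slope = (k2 - k1) / (m2 - m1)
    intercept = k1 - slope * m1
    return NormalizationModel(slope, intercept, (float(k1), float(k2)), (float(m1), float(m2)))


@dataclass(frozen=True)
class SpeciesIsotopeSummary:
    """Per-species mean and max-minus-min range of both isotopes at one site."""

    species: str
    site: str
    mean_d15N: float
    mean_d13C: float
    range_d15N: float
    range_d13C: float
    n: int
    below_min_n: bool = False


@dataclass(frozen=True)
class CommunitySummary:
    """All species summaries at one site plus community-level ranges, the
    max-minus-min spread of the species means."""

    site: str
    summaries: tuple[SpeciesIsotopeSummary, ...]
    community_range_d15N: float
    community_range_d13C: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "species": s.species,
                    "site": s.site,
                    "mean_d15N": s.mean_d15N,
                    "mean_d13C": s.mean_d13C,
                    "range_d15N": s.range_d15N,
                    "range_d13C": s.range_d13C,
                    "n": s.n,
                    "below_min_n": s.below_min_n,
                }
                for s in self.summaries
            ]
        )
        return df

    def species_means(self, isotope: str) -> pd.Series:
        col = {"d15N": "mean_d15N", "d13C": "mean_d13C"}[isotope]
        df = self.to_frame()
        return pd.Series(df[col].to_numpy(), index=df["species"].to_numpy())


def summarize_species(
    measurements: Sequence[IsotopeMeasurement],
    site: str,
    *,
    min_n: int = 1,
) -> CommunitySummary:
    """Species-level isotopic summaries for one site.

    Means and max-minus-min ranges are computed per species over individuals;
    the community ranges are the spread of the species means.  Species with
    fewer than ``min_n`` individuals are flagged (not dropped) so downstream
    filters can act on the flag.
    """
    at_site = [m for m in measurements if m.site == site]
    if not at_site:
        raise AnalysisError(f"no measurements at site {site!r}")
    df = pd.DataFrame(
        {
            "species": [m.species for m in at_site],
            "d15N": [m.d15N for m in at_site],
            "d13C": [m.d13C for m in at_site],
        }
    )
    rows = []
    for species, g in df.groupby("species", sort=True):
        rows.append(
            SpeciesIsotopeSummary(
                species=str(species),
                site=site,
                mean_d15N=float(g["d15N"].mean()),
                mean_d13C=float(g["d13C"].mean()),
                range_d15N=float(g["d15N"].max() - g["d15N"].min()),
                range_d13C=float(g["d13C"].max() - g["d13C"].min()),
                n=int(len(g)),
                below_min_n=len(g) < min_n,
            )
        )
    mean15 = np.array([r.mean_d15N for r in rows])
    mean13 = np.array([r.mean_d13C for r in rows])
    return CommunitySummary(
        site=site,
        summaries=tuple(rows),
        community_range_d15N=float(mean15.max() - mean15.min()),
        community_range_d13C=float(mean13.max() - mean13.min()),
    )


def trophic_transfers(
    d15N_high: float, d15N_low: float, cfg: AnalysisConfig | None = None
) -> float:
    """Number of trophic transfers implied by a d15N difference.

    ``(d15N_high - d15N_low) / enrichment_per_transfer``; the number of
    trophic *levels* spanned is this value plus one.  A negative result simply
    signals that the inputs were passed in reversed order.
    """
    cfg = cfg or AnalysisConfig()
    return (d15N_high - d15N_low) / cfg.enrichment_per_transfer


def levels_spanned(d15N_high: float, d15N_low: float, cfg: AnalysisConfig | None = None) -> float:
    return trophic_transfers(d15N_high, d15N_low, cfg) + 1.0


def apply_preservation_offset(
    measurements: Sequence[IsotopeMeasurement], cfg: AnalysisConfig
) -> list[IsotopeMeasurement]:
    """Subtract the configured ethanol-preservation d13C offset from every
    measurement (d15N untouched).  Offset 0 returns equal-valued records."""
    if not np.isfinite(cfg.ethanol_d13C_offset):
        raise ValidationError("ethanol_d13C_offset must be finite")
    return [replace(m, d13C=m.d13C - cfg.ethanol_d13C_offset) for m in measurements]
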