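"""Bundled reference tables.

Two small published summary tables for the arid-Australian sphenomorphine
skink communities (Lorna Glen and Yamarna) ship with the package: per-site
species mean/range isotope signatures, and a per-species diet summary
(major prey, its proportion and rank, and the weighted trophic rank).  The
63-category prey trophic coding is a *reconstruction*: only exemplar ranks
for the coding scheme are published, so the bundled CSV assigns the
remaining categories from the scheme's definitions (editable by users).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import TrophicCoding

__all__ = [
    "load_species_isotope_means",
    "load_diet_summary",
    "load_trophic_coding",
]


def _data_path(name: str):
    return resources.files("isotroph.data").joinpath(name)


def load_species_isotope_means() -> pd.DataFrame:
    """Published per-site species means and ranges of d15N/d13C (per mil)."""
    with resources.as_file(_data_path("skink_species_isotope_means.csv")) as p:
        return pd.read_csv(p)


def load_diet_summary() -> pd.DataFrame:
    """Published per-species stomach-content summary with weighted trophic rank."""
    with resources.as_file(_data_path("skink_diet_summary.csv")) as p:
        return pd.read_csv(p)


def load_trophic_coding() -> TrophicCoding:
    """Reconstructed 63-category prey trophic coding (see module docstring)."""
    from .io import read_trophic_coding

    with resources.as_file(_data_path("prey_trophic_coding.csv")) as p:
        return read_trophic_coding(p)
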