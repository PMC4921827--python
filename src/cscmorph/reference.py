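"""Packaged published measurement tables, consumed as inputs.

The raw micrographs and the MD-refined atomic models behind the published
cohort statistics are not deposited, so those numbers cannot be
recomputed from data.  They are shipped here as plain TSV inputs — the
dimensional summary of imaged rosette CSCs (per-geometry perimeter /
diameter / lobe-area rows), the predicted oligomer cross-sectional areas
of the two CESA transmembrane models, and a handful of published scalar
dimensions — so the arithmetic built on them stays reproducible.  Every
derived quantity (means of means, percent comparisons, the stoichiometry
call) is recomputed at run time from these inputs, never stored.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("cscmorph.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


@lru_cache(maxsize=None)
def dimension_table() -> pd.DataFrame:
    """Published per-geometry dimensions of imaged rosette CSCs.

    Columns: group, geometry, supergroup, perimeter_nm (+sd), diameter_nm
    (+sd), lobe_area_nm2 (+sd), n_particles, n_lobes.  The printed summary
    rows (means of means) are deliberately absent; they are recomputed.
    """
    return _read("table1.tsv")


@lru_cache(maxsize=None)
def oligomer_area_table() -> pd.DataFrame:
    """Published transmembrane cross-sectional areas of modeled oligomers.

    Tidy columns: model ('8tmh' | '7tmh_cesa'), order (2..6), area_nm2.
    """
    return _read("table2.tsv")


@lru_cache(maxsize=None)
def published_scalars() -> dict[str, float]:
    """Miscellaneous published dimensions keyed by name."""
    df = _read("published_scalars.tsv")
    return dict(zip(df["name"], df["value"].astype(float)))


def oligomer_areas(model: str) -> dict[int, float]:
    """``{order: area_nm2}`` for one published model row."""
    df = oligomer_area_table()
    sub = df[df["model"] == model]
    if sub.empty:
        raise KeyError(f"unknown model {model!r}; have {sorted(df['model'].unique())}")
    return dict(zip(sub["order"].astype(int), sub["area_nm2"].astype(float)))
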