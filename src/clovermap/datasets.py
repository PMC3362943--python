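"""Bundled reference tables for the white-clover EST-SSR marker panel.

Small published summary tables (motif counts of the mined SSR set, marker
screening outcomes, and the integrated-map per-group summary) shipped as
package data.  They serve as inputs to the report arithmetic — the mining
and mapping machinery never reads them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("clovermap").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_motif_counts() -> pd.DataFrame:
    """Mined SSR counts and designed-primer counts per motif class.

    Columns: motif, unit_len, n_ssr, designed_m0/m1/m2 (primer pairs
    designed on perfect / 1-mismatch / 2-mismatch tracts).  The mined set
    totals 1266 SSRs found in 6.0 Mbp of non-redundant EST sequence.
    """
    return _load("wcs_motif_counts.tsv")


MOTIF_TOTAL_BASES = 6_000_000


def load_marker_screening() -> pd.DataFrame:
    """Marker screening and mapping outcomes per marker source panel."""
    return _load("wcs_marker_screening.tsv").set_index("source")


def load_integrated_map_summary() -> pd.DataFrame:
    """Integrated-map locus counts and lengths per linkage group."""
    return _load("wcs_integrated_map_summary.tsv")
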