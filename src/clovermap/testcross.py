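"""Pseudo-testcross preparation: parental channel splitting, segregation
distortion testing, and polymorphism summary statistics.

In a full-sib F1 of an outcrossing (here allotetraploid) species, loci fall
into three segregation classes: heterozygous in the female parent only,
in the male parent only, or in both.  Splitting by class yields two
haploid-coded data sets, one per parental meiosis; bi-parental loci enter
both sets and later bridge the two parental maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .linkage import MISSING
from .ssr import round_half_up

log = logging.getLogger(__name__)

__all__ = [
    "PhasedLocus",
    "split_parental",
    "test_distortion",
    "summarize_polymorphism",
]

BIPARENTAL = "biparental"
FEMALE = "female"
MALE = "male"


@dataclass
class PhasedLocus:
    """One parental meiosis channel of a marker locus, haploid-coded.

    ``calls`` is an int8 vector over progeny: 0 = a, 1 = b, -1 = missing.
    The a/b labelling is arbitrary; phase is resolved pairwise downstream.
    """

    locus_id: str
    marker_id: str
    parent: str  # 'P1' (female) or 'P2' (male)
    calls: np.ndarray
    band_count: int = 1
    chi2: float = float("nan")
    p_value: float = float("nan")
    distorted: bool = False
    testable: bool = True

    @property
    def n_informative(self) -> int:
        return int((self.calls >= 0).sum())


def test_distortion(calls: np.ndarray, alpha: float = 0.05
                    ) -> tuple[float, float, bool]:
    """Chi-square test of the 1:1 testcross ratio (1 df, no continuity
    correction); missing calls are excluded.

    Returns (chi2, p, distorted); with zero informative calls the statistic
    is NaN and the locus is reported untestable (not distorted).
    """
    calls = np.asarray(calls)
    na = int((calls == 0).sum())
    nb = int((calls == 1).sum())
    n = na + nb
    if n == 0:
        return float("nan"), float("nan"), False
    chi2 = (na - nb) ** 2 / n
    p = float(sstats.chi2.sf(chi2, df=1))
    return float(chi2), p, p < alpha


def split_parental(table, alpha: float = 0.05,
                   min_informative_frac: float = 0.2
                   ) -> tuple[list[PhasedLocus], list[PhasedLocus]]:
    """Split a genotype table into the two parental-specific haploid sets.

    Female-class rows go to P1, male-class rows to P2, and bi-parental rows
    contribute one phased locus to each set (with a parent suffix on the
    locus id, sharing the marker id — these are the integration bridges).
    Rows that are all-missing, or informative in fewer than
    ``min_informative_frac`` of progeny, are excluded with a warning.
    Distortion is tested on every retained locus.
    """
    n_prog = len(table.progeny_ids)
    p1: list[PhasedLocus] = []
    p2: list[PhasedLocus] = []

    def make(row, parent: str, suffix: str = "") -> PhasedLocus | None:
        calls = np.asarray(row.calls[parent], dtype=np.int8)
        n_inf = int((calls >= 0).sum())
        if n_inf == 0:
            log.warning("locus %s (%s): all calls missing; excluded",
                        row.locus_id, parent)
            return None
        if n_inf < min_informative_frac * n_prog:
            log.warning("locus %s (%s): only %d informative progeny; excluded",
                        row.locus_id, parent, n_inf)
            return None
        lo = PhasedLocus(locus_id=row.locus_id + suffix,
                         marker_id=row.marker_id, parent=parent,
                         calls=calls, band_count=row.band_count)
        lo.chi2, lo.p_value, lo.distorted = test_distortion(calls, alpha)
        lo.testable = np.isfinite(lo.chi2)
        return lo

    for row in table.rows:
        if row.seg_class == FEMALE:
            lo = make(row, "P1")
            if lo:
                p1.append(lo)
        elif row.seg_class == MALE:
            lo = make(row, "P2")
            if lo:
                p2.append(lo)
        elif row.seg_class == BIPARENTAL:
            lo1 = make(row, "P1", suffix="_P1")
            lo2 = make(row, "P2", suffix="_P2")
            if lo1:
                p1.append(lo1)
            if lo2:
                p2.append(lo2)
        else:
            raise ValueError(f"unknown segregation class {row.seg_class!r} "
                             f"at locus {row.locus_id}")
    return p1, p2


def summarize_polymorphism(sources: pd.DataFrame | Mapping[str, Mapping[str, int]]
                           ) -> pd.DataFrame:
    """Per-source polymorphism and mapping summary.

    Input columns (or inner dict keys): n_screened, n_polymorphic,
    n_mapped_markers, n_mapped_loci.  Adds a Total row plus the derived
    polymorphic ratio (%, half-up to 1 decimal; blank when nothing was
    screened) and average mapped loci per mapped marker (1 decimal).
    """
    if not isinstance(sources, pd.DataFrame):
        sources = pd.DataFrame.from_dict(sources, orient="index")
    df = sources.copy()
    total = df[["n_screened", "n_polymorphic", "n_mapped_markers",
                "n_mapped_loci"]].sum()
    df.loc["Total"] = total

    def ratio(row):
        if row["n_screened"] == 0:
            return float("nan")
        return round_half_up(100.0 * row["n_polymorphic"] / row["n_screened"], 1)

    def lpm(row):
        if row["n_mapped_markers"] == 0:
            return float("nan")
        return round_half_up(row["n_mapped_loci"] / row["n_mapped_markers"], 1)

    df["polymorphic_ratio_pct"] = df.apply(ratio, axis=1)
    df["loci_per_marker"] = df.apply(lpm, axis=1)
    return df
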