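"""Mismatch-tolerant SSR (microsatellite) mining in transcript sequences.

Finds maximal tracts of di-, tri- and tetra-nucleotide repeats of total
length >= 15 nt, either perfect or containing up to 1-2 base substitutions
(no indels), collapses motifs to a canonical strand/phase class, summarises
motif frequencies and SSR density, and flags tracts around which a PCR
marker with a 90-300 bp amplicon could be designed.

Coordinates are 1-based inclusive throughout, matching the usual reporting
convention for marker development.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SSRHit",
    "MotifReport",
    "canonical_motif",
    "find_ssrs",
    "summarize_motifs",
    "summarize_designed",
    "flag_designable",
    "round_half_up",
]

_COMP = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the convention used in printed report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _is_primitive(unit: str) -> bool:
    """A unit is primitive when it is not a repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonical_motif(unit: str) -> str:
    """Canonical motif class: lexicographic minimum over all rotations of
    the unit and of its reverse complement (collapses strand and phase)."""
    unit = unit.upper()
    rc = revcomp(unit)
    rots = [unit[k:] + unit[:k] for k in range(len(unit))]
    rots += [rc[k:] + rc[:k] for k in range(len(rc))]
    return min(rots)


def _primitive_units(unit_lens: Iterable[int] = (2, 3, 4)) -> list[str]:
    import itertools

    units = []
    for u in unit_lens:
        for tup in itertools.product(_BASES, repeat=u):
            w = "".join(tup)
            if _is_primitive(w):
                units.append(w)
    return units


_UNITS = _primitive_units()


@dataclass
class SSRHit:
    """One repeat tract: 1-based inclusive coordinates on the input strand."""

    seq_id: str
    start: int
    end: int
    unit_len: int
    canonical_motif: str
    tract_len: int
    n_mismatches: int
    designable: bool | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _candidate_windows(match: np.ndarray, k: int, min_len: int):
    """Maximal windows with <= k non-matching positions, ends on a match.

    ``match`` is a boolean array; yields (start, end_exclusive, n_mismatch).
    """
    n = len(match)
    mism = np.flatnonzero(~match)
    z = np.concatenate([[-1], mism, [n]])
    nm = len(mism)
    # maximal window containing the mismatches z[t+1..t+kk] (count <= k),
    # then trimmed so both ends land on a matching base
    kk = min(k, nm)
    for t in range(nm - kk + 1):
        lo = int(z[t]) + 1
        hi = int(z[t + kk + 1])  # exclusive
        while lo < hi and not match[lo]:
            lo += 1
        while hi > lo and not match[hi - 1]:
            hi -= 1
        if hi - lo < min_len:
            continue
        yield lo, hi, int((~match[lo:hi]).sum())


def find_ssrs(sequence: str, seq_id: str = "seq", min_len: int = 15,
              max_mismatch: int = 0) -> list[SSRHit]:
    """Find maximal SSR tracts with at most ``max_mismatch`` substitutions.

    A tract qualifies when some phase of a primitive 2-4 nt repeat unit
    matches it with Hamming distance <= max_mismatch, its length is
    >= min_len, and its first and last bases match the unit ('N' never
    matches).  Overlapping candidates are resolved greedily: longest tract
    wins, ties broken by fewer mismatches, then leftmost start.  Each
    retained hit reports the minimal mismatch count over units achieving its
    interval.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < min_len:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    base_eq = {b: arr == ord(b) for b in _BASES}

    # best (n_mismatch, canonical motif) per interval
    best: dict[tuple[int, int], tuple[int, str]] = {}
    pos_idx = np.arange(n)
    pos_mod = {u: pos_idx % u for u in (2, 3, 4)}
    eq_stack = np.stack([base_eq[b] for b in _BASES])
    for unit in _UNITS:
        u = len(unit)
        codes = np.array([_BASES.index(c) for c in unit])
        # match[i] = seq[i] == unit[i mod u]
        match = eq_stack[codes[pos_mod[u]], pos_idx]
        mism_total = n - int(match.sum())
        for k in range(0, max_mismatch + 1):
            if k > 0 and mism_total < k:
                break
            for lo, hi, _ in _candidate_windows(match, k, min_len):
                iv = (lo, hi)
                nm = int((~match[lo:hi]).sum())
                cm = canonical_motif(unit)
                prev = best.get(iv)
                if prev is None or (nm, cm) < prev:
                    best[iv] = (nm, cm)

    cands = [
        SSRHit(seq_id=seq_id, start=lo + 1, end=hi, unit_len=len(best[(lo, hi)][1]),
               canonical_motif=best[(lo, hi)][1], tract_len=hi - lo,
               n_mismatches=best[(lo, hi)][0])
        for (lo, hi) in best
    ]
    # overlap resolution: longest, then fewest mismatches, then leftmost
    cands.sort(key=lambda h: (-h.tract_len, h.n_mismatches, h.start))
    kept: list[SSRHit] = []
    for h in cands:
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def find_ssrs_fasta(records, min_len: int = 15, max_mismatch: int = 0
                    ) -> list[SSRHit]:
    """Run :func:`find_ssrs` over Biopython SeqRecords (or (id, seq) pairs)."""
    hits: list[SSRHit] = []
    for rec in records:
        sid, seq = (rec.id, str(rec.seq)) if hasattr(rec, "seq") else rec
        hits.extend(find_ssrs(seq, seq_id=sid, min_len=min_len,
                              max_mismatch=max_mismatch))
    return hits


@dataclass
class MotifReport:
    """Motif-class frequency summary of a set of SSR tracts.

    ``density_bp`` is the number of input bases per SSR (None when there are
    no hits); percentages use half-up rounding at reporting time only — the
    stored fields are exact.
    """

    motif_counts: dict[str, int]
    total_bases: int
    unit_len_of: dict[str, int] = field(default_factory=dict)

    @property
    def n_hits(self) -> int:
        return sum(self.motif_counts.values())

    @property
    def density_bp(self) -> float | None:
        n = self.n_hits
        return self.total_bases / n if n else None

    def motif_percent(self, motif: str, ndigits: int = 2) -> float:
        return round_half_up(100.0 * self.motif_counts.get(motif, 0)
                             / self.n_hits, ndigits)

    def unit_class_counts(self) -> dict[int, int]:
        out = {2: 0, 3: 0, 4: 0}
        for m, c in self.motif_counts.items():
            out[self.unit_len_of.get(m, len(m))] += c
        return out

    def unit_class_percent(self, ndigits: int = 1) -> dict[int, float]:
        tot = self.n_hits
        return {u: round_half_up(100.0 * c / tot, ndigits) if tot else float("nan")
                for u, c in self.unit_class_counts().items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"motif": m, "unit_len": self.unit_len_of.get(m, len(m)),
                 "count": c,
                 "percent": self.motif_percent(m)}
                for m, c in sorted(self.motif_counts.items(),
                                   key=lambda kv: (-kv[1], kv[0]))]
        return pd.DataFrame(rows, columns=["motif", "unit_len", "count", "percent"])

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], total_bases: int,
                    unit_len_of: Mapping[str, int] | None = None) -> "MotifReport":
        ulo = dict(unit_len_of) if unit_len_of else {m: len(m) for m in counts}
        return cls(motif_counts=dict(counts), total_bases=int(total_bases),
                   unit_len_of=ulo)


def summarize_motifs(hits: Sequence[SSRHit], total_bases: int) -> MotifReport:
    """Tally hits by canonical motif class and compute SSR density."""
    counts: dict[str, int] = {}
    ulo: dict[str, int] = {}
    for h in hits:
        counts[h.canonical_motif] = counts.get(h.canonical_motif, 0) + 1
        ulo[h.canonical_motif] = h.unit_len
    return MotifReport(motif_counts=counts, total_bases=int(total_bases),
                       unit_len_of=ulo)


def summarize_designed(designed: Mapping[str, int],
                       unit_len_of: Mapping[str, int] | None = None
                       ) -> pd.DataFrame:
    """Summarise designed-marker counts per motif.

    ``designed`` maps motif class -> number of designed primer pairs.
    Returns a frame with each motif's share of its unit-length class and of
    the grand total (exact fractions; round at reporting time).
    """
    ulo = dict(unit_len_of) if unit_len_of else {m: len(m) for m in designed}
    total = sum(designed.values())
    class_tot = {u: 0 for u in (2, 3, 4)}
    for m, c in designed.items():
        class_tot[ulo[m]] += c
    rows = []
    for m, c in sorted(designed.items(), key=lambda kv: (-kv[1], kv[0])):
        u = ulo[m]
        rows.append({
            "motif": m, "unit_len": u, "count": c,
            "pct_of_class": 100.0 * c / class_tot[u] if class_tot[u] else float("nan"),
            "pct_of_total": 100.0 * c / total if total else float("nan"),
        })
    return pd.DataFrame(rows, columns=["motif", "unit_len", "count",
                                       "pct_of_class", "pct_of_total"])


def flag_designable(hits: Sequence[SSRHit], seq_lengths: Mapping[str, int],
                    amplicon: tuple[int, int] = (90, 300),
                    min_flank: int = 20) -> list[SSRHit]:
    """Flag tracts around which a marker amplicon is feasible.

    A hit is designable when both flanks hold >= ``min_flank`` non-SSR
    bases, the minimal amplicon (tract + 2*min_flank) fits under the upper
    amplicon bound, and an amplicon reaching the lower bound fits inside the
    sequence.  Mutates and returns the hits.
    """
    amin, amax = amplicon
    for h in hits:
        L = seq_lengths[h.seq_id]
        left = h.start - 1
        right = L - h.end
        minimal = h.tract_len + 2 * min_flank
        h.designable = (
            left >= min_flank and right >= min_flank
            and minimal <= amax
            and max(amin, minimal) <= L
        )
    return list(hits)
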