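"""File formats: genotype tables, homolog hit tables, genetic maps, links.

All formats are plain TSV.  Genomic bp coordinates are 1-based inclusive
(BLAST convention); map positions are nonnegative floats in cM.  Missing
genotype calls may be written with any configured alias but are normalised
to the single canonical symbol '-' (internally int8 -1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .linkage import MISSING

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeRow",
    "GenotypeTable",
    "read_genotype_table",
    "write_genotype_table",
    "read_hit_table",
    "best_hits",
    "read_map",
    "write_map",
    "write_links",
]

MISSING_SYMBOL = "-"
DEFAULT_MISSING_ALIASES = ("-", "—", "NA", "na", ".", "")

_CALL_CODE = {"a": 0, "b": 1}
_CODE_CALL = {0: "a", 1: "b", MISSING: MISSING_SYMBOL}


@dataclass
class GenotypeRow:
    """One locus: segregation class plus per-parent haploid call vectors.

    ``calls`` maps 'P1'/'P2' to int8 vectors (0=a, 1=b, -1=missing);
    bi-parental loci carry both channels, parent-specific loci one.
    """

    locus_id: str
    marker_id: str
    seg_class: str  # biparental | female | male
    band_count: int
    calls: dict[str, np.ndarray]


@dataclass
class GenotypeTable:
    """Locus x progeny genotype table for a full-sib F1 family."""

    progeny_ids: list[str]
    rows: list[GenotypeRow]

    @property
    def n_progeny(self) -> int:
        return len(self.progeny_ids)

    def validate(self) -> "GenotypeTable":
        seen = set()
        for row in self.rows:
            if row.locus_id in seen:
                raise ValueError(f"duplicate locus_id {row.locus_id!r}")
            seen.add(row.locus_id)
            expect = {"biparental": ("P1", "P2"), "female": ("P1",),
                      "male": ("P2",)}.get(row.seg_class)
            if expect is None:
                raise ValueError(f"unknown segregation class "
                                 f"{row.seg_class!r} at locus {row.locus_id}")
            if tuple(sorted(row.calls)) != tuple(sorted(expect)):
                raise ValueError(
                    f"locus {row.locus_id}: class {row.seg_class} requires "
                    f"call vectors for {expect}, found {tuple(row.calls)}")
            for parent, vec in row.calls.items():
                if len(vec) != self.n_progeny:
                    raise ValueError(
                        f"locus {row.locus_id} ({parent}): {len(vec)} calls "
                        f"for {self.n_progeny} progeny")
            if row.band_count < 1:
                raise ValueError(f"locus {row.locus_id}: band_count must be >= 1")
        return self


def read_genotype_table(path, missing_aliases: Sequence[str] = DEFAULT_MISSING_ALIASES
                        ) -> GenotypeTable:
    """Read a genotype table TSV (comma also accepted).

    Layout: header ``locus_id marker_id seg_class parent band_count`` then one
    column per progeny; one data row per locus x parental channel (bi-parental
    loci appear as two rows sharing locus_id).  Unknown call symbols raise a
    hard error naming the row and column.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty genotype table")
    delim = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(delim)
    fixed = ["locus_id", "marker_id", "seg_class", "parent", "band_count"]
    if header[: len(fixed)] != fixed:
        raise ValueError(f"{path}: header must begin with {fixed}")
    progeny_ids = header[len(fixed):]
    if not progeny_ids:
        raise ValueError(f"{path}: no progeny columns")
    aliases = set(missing_aliases) | {MISSING_SYMBOL}

    parsed: dict[str, dict] = {}
    order: list[str] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split(delim)
        if len(parts) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} "
                             f"fields, found {len(parts)}")
        lid, mid, seg, parent, bands = parts[:5]
        vec = np.empty(len(progeny_ids), dtype=np.int8)
        for k, sym in enumerate(parts[5:]):
            sym = sym.strip()
            if sym in aliases:
                vec[k] = MISSING
            elif sym in _CALL_CODE:
                vec[k] = _CALL_CODE[sym]
            else:
                raise ValueError(
                    f"{path}:{lineno}: unknown call symbol {sym!r} at locus "
                    f"{lid}, progeny {progeny_ids[k]}")
        if lid not in parsed:
            parsed[lid] = {"marker_id": mid, "seg_class": seg,
                           "band_count": int(bands), "calls": {}}
            order.append(lid)
        if parent in parsed[lid]["calls"]:
            raise ValueError(f"{path}:{lineno}: duplicate locus_id {lid!r} "
                             f"for parent {parent}")
        parsed[lid]["calls"][parent] = vec

    rows = [GenotypeRow(locus_id=lid, marker_id=p["marker_id"],
                        seg_class=p["seg_class"], band_count=p["band_count"],
                        calls=p["calls"])
            for lid, p in ((l, parsed[l]) for l in order)]
    return GenotypeTable(progeny_ids=progeny_ids, rows=rows).validate()


def write_genotype_table(table: GenotypeTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        head = ["locus_id", "marker_id", "seg_class", "parent", "band_count"]
        fh.write("\t".join(head + table.progeny_ids) + "\n")
        for row in table.rows:
            for parent in sorted(row.calls):
                syms = [_CODE_CALL[int(c)] for c in row.calls[parent]]
                fh.write("\t".join([row.locus_id, row.marker_id,
                                    row.seg_class, parent,
                                    str(row.band_count)] + syms) + "\n")


_HIT_COLS = ["query_id", "reference_id", "chromosome", "start_bp", "end_bp",
             "evalue", "bitscore"]


def read_hit_table(path, evalue_max: float | None = None) -> pd.DataFrame:
    """Read a BLAST-outfmt6-like hit table.

    Two dialects are accepted: the standard 12 columns (qseqid sseqid pident
    length mismatch gapopen qstart qend sstart send evalue bitscore), where
    the subject id doubles as the chromosome and sstart/send give the
    coordinates; or a 15-column extension with explicit
    chromosome/start_bp/end_bp appended.  Records with evalue > evalue_max
    are dropped.  Returns a DataFrame with columns {}.
    """.format(_HIT_COLS)
    path = Path(path)
    recs = []
    with path.open() as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            try:
                if len(parts) == 12:
                    q, s = parts[0], parts[1]
                    sstart, send = int(parts[8]), int(parts[9])
                    ev, bs = float(parts[10]), float(parts[11])
                    chrom = s
                elif len(parts) == 15:
                    q, s = parts[0], parts[1]
                    ev, bs = float(parts[10]), float(parts[11])
                    chrom = parts[12]
                    sstart, send = int(parts[13]), int(parts[14])
                else:
                    raise ValueError(f"expected 12 or 15 fields, "
                                     f"found {len(parts)}")
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: unparseable hit row "
                                 f"({e})") from None
            lo, hi = (sstart, send) if sstart <= send else (send, sstart)
            if ev < 0:
                raise ValueError(f"{path}:{lineno}: negative E-value")
            recs.append((q, s, chrom, lo, hi, ev, bs))
    df = pd.DataFrame(recs, columns=_HIT_COLS)
    if evalue_max is not None and len(df):
        kept = df[df["evalue"] <= evalue_max].reset_index(drop=True)
        log.info("hit table %s: %d of %d records pass E <= %g",
                 path.name, len(kept), len(df), evalue_max)
        df = kept
    return df


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One best hit per query: max bitscore, ties broken by smaller evalue,
    then lexicographic reference_id."""
    if not len(hits):
        return hits.copy()
    df = hits.sort_values(
        ["query_id", "bitscore", "evalue", "reference_id"],
        ascending=[True, False, True, True], kind="mergesort")
    return df.groupby("query_id", as_index=False).head(1).reset_index(drop=True)


MAP_COLS = ["group", "locus_id", "marker_id", "position_cm", "seg_class",
            "distorted"]


def write_map(map_df: pd.DataFrame, path) -> None:
    df = map_df.copy()
    df["position_cm"] = df["position_cm"].map(lambda x: f"{x:.3f}")
    df["distorted"] = df["distorted"].map(lambda b: "1" if b else "0")
    df[MAP_COLS].to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "locus_id": str,
                                            "marker_id": str})
    df["position_cm"] = df["position_cm"].astype(float)
    df["distorted"] = df["distorted"].astype(int).astype(bool)
    return df


def write_links(blocks, path) -> None:
    """Circos-style synteny link text: lg start_cm end_cm chrom start_bp end_bp."""
    with Path(path).open("w") as fh:
        for b in blocks:
            fh.write(f"{b.group} {b.start_cm:.3f} {b.end_cm:.3f} "
                     f"{b.chromosome} {b.start_bp} {b.end_bp}\n")
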