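"""Synthetic data generation for the full pipeline, with known truth.

Emulates the inputs of a two-way pseudo-testcross mapping experiment in an
allotetraploid (2 subgenomes x 8 chromosomes = 16 linkage groups):

* an F1 genotype table for ``n_progeny`` full sibs, with bi-parental /
  female-specific / male-specific loci, multi-locus (homeolog-duplicated)
  markers, viability segregation distortion, call errors, missing data and
  optionally planted cross-chromosome gametic disequilibrium;
* transcript FASTA with planted perfect or mismatch SSR tracts;
* a colinear (optionally rearranged) synthetic reference genome with a
  homolog hit table.

Meiosis is modelled as a Markov chain over the ordered loci of each group:
adjacent-interval recombination probability is the Kosambi inverse of the
cM gap, with crossovers independent across intervals and groups independent
except for planted LD anchor pairs, whose joint allele distribution has the
requested coupling D'.  Every generated item is recorded in a
:class:`SimTruth` sufficient to score downstream inference exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeRow, GenotypeTable
from .linkage import MISSING, kosambi_inverse

log = logging.getLogger(__name__)

__all__ = [
    "SimGenome",
    "SimDesign",
    "PlantedLD",
    "SimTruth",
    "simulate_gametes",
    "render_genotype_table",
    "simulate_transcripts",
    "simulate_reference",
    "simulate_dataset",
]


@dataclass
class PlantedLD:
    """Cross-group disequilibrium planted between two anchor loci of one
    parent's meioses; ``dprime`` is the coupling D' in [-1, 1]."""

    parent: str
    group_a: str
    pos_a_cm: float
    group_b: str
    pos_b_cm: float
    dprime: float


@dataclass
class SimGenome:
    """Marker layout of the simulated allotetraploid genome.

    Homeolog pair partners share their marker position grid, so a
    duplicated marker occupies the same position index on both partners.
    ``chrom_of_group`` maps each linkage group to its (shared) ancestral
    reference chromosome.
    """

    n_homeolog_pairs: int
    group_lengths_cm: dict[str, float]
    marker_positions: dict[str, np.ndarray]
    homeolog_pairs: list[tuple[str, str]]
    chrom_of_group: dict[str, str]

    def validate(self) -> "SimGenome":
        seen: set[str] = set()
        for a, b in self.homeolog_pairs:
            if a in seen or b in seen:
                raise ValueError("homeolog pairs must be a perfect matching")
            seen.update((a, b))
        if seen != set(self.group_lengths_cm):
            raise ValueError("every group must belong to exactly one pair")
        for g, pos in self.marker_positions.items():
            if len(pos) < 2:
                raise ValueError(f"group {g} has fewer than 2 markers")
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"group {g} positions not sorted")
        return self

    @property
    def groups(self) -> list[str]:
        return list(self.group_lengths_cm)

    @classmethod
    def regular(cls, n_pairs: int = 8, length_cm: float = 100.0,
                markers_per_group: int = 14,
                rng: np.random.Generator | None = None) -> "SimGenome":
        """Evenly spaced layout (slightly jittered when an rng is given)."""
        lengths: dict[str, float] = {}
        positions: dict[str, np.ndarray] = {}
        pairs: list[tuple[str, str]] = []
        chrom: dict[str, str] = {}
        for p in range(1, n_pairs + 1):
            base = np.linspace(0.0, length_cm, markers_per_group)
            if rng is not None and markers_per_group > 2:
                step = length_cm / (markers_per_group - 1)
                jit = rng.uniform(-0.3 * step, 0.3 * step,
                                  markers_per_group - 2)
                base = base.copy()
                base[1:-1] = np.sort(base[1:-1] + jit)
            ga, gb = f"LG{p}a", f"LG{p}b"
            pairs.append((ga, gb))
            for g in (ga, gb):
                lengths[g] = float(length_cm)
                positions[g] = base.copy()
                chrom[g] = f"chr{p}"
        return cls(n_homeolog_pairs=n_pairs, group_lengths_cm=lengths,
                   marker_positions=positions, homeolog_pairs=pairs,
                   chrom_of_group=chrom).validate()


@dataclass
class SimDesign:
    """Study design: sample size, locus class counts, and noise levels.

    Defaults are the emulated study's conditions: 188 progeny and
    424 / 789 / 584 bi-parental / female-specific / male-specific loci.
    ``distortion_loci`` holds (parent, group, pos_cm, s) tuples where ``s``
    is a gametic viability selection coefficient against allele b.
    """

    n_progeny: int = 188
    n_biparental: int = 424
    n_female: int = 789
    n_male: int = 584
    multi_locus_fraction: float = 0.3
    missing_rate: float = 0.05
    error_rate: float = 0.01
    distortion_loci: list[tuple] = field(default_factory=list)
    planted_ld: list[PlantedLD] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> "SimDesign":
        for name in ("multi_locus_fraction", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_progeny < 2:
            raise ValueError("n_progeny must be >= 2")
        for pl in self.planted_ld:
            if not -1.0 <= pl.dprime <= 1.0:
                raise ValueError(f"|D'| must be <= 1, got {pl.dprime}")
        for (_p, _g, _pos, s) in self.distortion_loci:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"selection coefficient {s} outside [0, 1]")
        return self

    @property
    def n_loci(self) -> int:
        return self.n_biparental + self.n_female + self.n_male


@dataclass
class SimTruth:
    """Everything needed to score downstream inference exactly."""

    loci: pd.DataFrame           # locus_id, marker_id, group, pos_cm, seg_class, band_count
    gametes: dict                # parent -> group -> (m_group x n) int8 pre-noise haplotypes
    genome: SimGenome
    design: SimDesign
    progeny_resample: np.ndarray | None = None  # indices used under distortion
    reference: pd.DataFrame | None = None       # marker truth positions on reference
    hits: pd.DataFrame | None = None            # synthetic homolog hit table

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.loci["locus_id"], self.loci["group"]))


def _walk_from(anchor_allele: np.ndarray, positions: np.ndarray,
               anchor_idx: int, rng: np.random.Generator) -> np.ndarray:
    """Conditional Markov walk outward from an anchor locus.

    Returns an (m, n) allele matrix whose row ``anchor_idx`` equals
    ``anchor_allele`` and whose adjacent-interval recombination follows the
    Kosambi inverse of the cM gaps.
    """
    m, n = len(positions), len(anchor_allele)
    out = np.empty((m, n), dtype=np.int8)
    out[anchor_idx] = anchor_allele
    r = kosambi_inverse(np.diff(positions))
    for k in range(anchor_idx - 1, -1, -1):
        flip = rng.random(n) < r[k]
        out[k] = out[k + 1] ^ flip
    for k in range(anchor_idx + 1, m):
        flip = rng.random(n) < r[k - 1]
        out[k] = out[k - 1] ^ flip
    return out


def simulate_gametes(genome: SimGenome, design: SimDesign, parent: str,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Simulate one parent's gametes for every progeny at every marker.

    Returns group -> (m_group, n_progeny) int8 allele matrices.  Groups are
    independent except for planted LD pairs of this parent: their two anchor
    alleles are drawn jointly with P(equal) = (1 + D')/2 (uniform margins),
    then the chromosome walks proceed conditionally outward from each anchor.
    """
    design.validate()
    genome.validate()
    n = design.n_progeny
    planted = [pl for pl in design.planted_ld if pl.parent == parent]

    def anchor_index(g: str, pos_cm: float) -> int:
        pos = genome.marker_positions[g]
        hits = np.flatnonzero(np.isclose(pos, pos_cm))
        if len(hits) == 0:
            raise ValueError(
                f"planted LD anchor at {pos_cm} cM is off any marker "
                f"position of group {g}")
        return int(hits[0])

    # pairs may share an anchor locus (star/chain topologies); alleles are
    # drawn sequentially, conditioning on any already-anchored side
    anchored: dict[str, tuple[int, np.ndarray]] = {}
    for pl in planted:
        ia = anchor_index(pl.group_a, pl.pos_a_cm)
        ib = anchor_index(pl.group_b, pl.pos_b_cm)
        a_known = pl.group_a in anchored
        b_known = pl.group_b in anchored
        if a_known and b_known:
            raise ValueError("planted LD pair with both anchors already set")
        if b_known:  # orient so the known side (if any) is 'a'
            pl = PlantedLD(pl.parent, pl.group_b, pl.pos_b_cm,
                           pl.group_a, pl.pos_a_cm, pl.dprime)
            ia, ib = ib, ia
            a_known = True
        if a_known:
            prev_idx, x = anchored[pl.group_a]
            if prev_idx != ia:
                raise ValueError(
                    f"group {pl.group_a} hosts two different LD anchor loci")
        else:
            x = rng.integers(0, 2, size=n, dtype=np.int8)
            anchored[pl.group_a] = (ia, x)
        same = rng.random(n) < (1.0 + pl.dprime) / 2.0
        y = np.where(same, x, 1 - x).astype(np.int8)
        anchored[pl.group_b] = (ib, y)

    out: dict[str, np.ndarray] = {}
    for g in genome.groups:
        pos = genome.marker_positions[g]
        if g in anchored:
            idx, allele = anchored[g]
            out[g] = _walk_from(allele, pos, idx, rng)
        else:
            start = rng.integers(0, 2, size=n, dtype=np.int8)
            out[g] = _walk_from(start, pos, 0, rng)
    return out


def assign_loci(genome: SimGenome, design: SimDesign,
                rng: np.random.Generator) -> pd.DataFrame:
    """Assign segregation classes and marker ids to genome positions.

    The genome must carry exactly ``design.n_loci`` marker positions.  A
    ``multi_locus_fraction`` of markers is duplicated onto the homeolog
    partner at the same position index (both loci share the marker id with
    'a'/'b' suffixed locus ids and band_count 2), emulating homeologous
    amplification of a single primer pair.
    """
    slots = [(g, k) for g in genome.groups
             for k in range(len(genome.marker_positions[g]))]
    if len(slots) != design.n_loci:
        raise ValueError(
            f"genome has {len(slots)} marker positions but the design "
            f"specifies {design.n_loci} loci")
    partner = {}
    for a, b in genome.homeolog_pairs:
        partner[a], partner[b] = b, a

    rng.shuffle(slots)
    used: set[tuple[str, int]] = set()
    records: list[dict] = []
    mk = 0
    for g, k in slots:
        if (g, k) in used:
            continue
        mk += 1
        marker = f"WCS{mk:04d}"
        dup = ((partner[g], k) not in used
               and rng.random() < design.multi_locus_fraction)
        if dup:
            used.update({(g, k), (partner[g], k)})
            for suffix, gg in (("a", g), ("b", partner[g])):
                records.append(dict(locus_id=marker + suffix, marker_id=marker,
                                    group=gg, idx=k,
                                    pos_cm=float(genome.marker_positions[gg][k]),
                                    band_count=2))
        else:
            used.add((g, k))
            records.append(dict(locus_id=marker, marker_id=marker, group=g,
                                idx=k, pos_cm=float(genome.marker_positions[g][k]),
                                band_count=1))
    loci = pd.DataFrame(records)  # one locus per slot, so exactly n_loci rows

    classes = (["biparental"] * design.n_biparental
               + ["female"] * design.n_female + ["male"] * design.n_male)
    classes = np.array(classes[: len(loci)])
    rng.shuffle(classes)
    loci["seg_class"] = classes
    return loci


def render_genotype_table(haplotypes: Mapping[str, Mapping[str, np.ndarray]],
                          loci: pd.DataFrame, design: SimDesign,
                          genome: SimGenome, rng: np.random.Generator
                          ) -> tuple[GenotypeTable, SimTruth]:
    """Turn true gametes into an observed genotype table.

    Applies, in order: viability distortion (progeny resampled with weight
    (1-s) per selected-against allele carried), segregation-class masking
    (parent-specific loci are observable on one channel only), symmetric
    call error, and missing-at-random masking.
    """
    design.validate()
    n = design.n_progeny
    weights = np.ones(n)
    for (parent, g, pos_cm, s) in design.distortion_loci:
        pos = genome.marker_positions[g]
        k = int(np.argmin(np.abs(pos - pos_cm)))
        allele = haplotypes[parent][g][k]
        weights *= np.where(allele == 1, 1.0 - s, 1.0)
    if np.any(weights < 1.0):
        idx = rng.choice(n, size=n, replace=True, p=weights / weights.sum())
    else:
        idx = np.arange(n)

    def observe(parent: str, g: str, k: int) -> np.ndarray:
        calls = haplotypes[parent][g][k][idx].copy()
        err = rng.random(n) < design.error_rate
        calls[err] ^= 1
        miss = rng.random(n) < design.missing_rate
        calls[miss] = MISSING
        return calls

    rows: list[GenotypeRow] = []
    for rec in loci.itertuples():
        channels: dict[str, np.ndarray] = {}
        if rec.seg_class in ("biparental", "female"):
            channels["P1"] = observe("P1", rec.group, rec.idx)
        if rec.seg_class in ("biparental", "male"):
            channels["P2"] = observe("P2", rec.group, rec.idx)
        rows.append(GenotypeRow(locus_id=rec.locus_id, marker_id=rec.marker_id,
                                seg_class=rec.seg_class,
                                band_count=int(rec.band_count), calls=channels))
    progeny_ids = [f"F1-{i + 1:03d}" for i in range(n)]
    table = GenotypeTable(progeny_ids=progeny_ids, rows=rows).validate()
    truth = SimTruth(loci=loci.copy(), gametes={p: dict(h) for p, h in
                                                haplotypes.items()},
                     genome=genome, design=design, progeny_resample=idx)
    return table, truth


# ---------------------------------------------------------------------------
# transcripts with planted SSR tracts

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_primitive_unit(u: int, rng: np.random.Generator) -> str:
    from .ssr import _is_primitive

    while True:
        w = "".join("ACGT"[c] for c in rng.integers(0, 4, size=u))
        if _is_primitive(w):
            return w


def simulate_transcripts(n: int, length_range: tuple[int, int] = (300, 1200),
                         plant_rate_per_kb: float = 1.0 / 4.7,
                         tract_len_range: tuple[int, int] = (15, 30),
                         mismatch_weights: tuple[float, float, float] = (1.0, 0.0, 0.0),
                         rng: np.random.Generator | None = None,
                         seed: int | None = None):
    """Uniform-random transcripts with planted SSR tracts.

    Tracts are planted at an expected density of ``plant_rate_per_kb`` per
    kb, with unit length drawn from {2, 3, 4}, mismatch count 0/1/2 drawn
    with ``mismatch_weights``, and the flanking bases forced to break the
    repeat so each planted tract is maximal.  Returns
    (list of Biopython SeqRecords, truth DataFrame with 1-based coords).
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from .ssr import canonical_motif

    if rng is None:
        rng = np.random.default_rng(seed)
    mw = np.asarray(mismatch_weights, dtype=float)
    mw = mw / mw.sum()
    records, truth = [], []
    for t in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _BASES[rng.integers(0, 4, size=L)].tobytes().decode()
        sid = f"TC{t + 1:05d}"
        n_plant = rng.poisson(plant_rate_per_kb * L / 1000.0)
        cursor = 5
        chars = list(seq)
        for _ in range(n_plant):
            u = int(rng.choice((2, 3, 4)))
            tlen = int(rng.integers(tract_len_range[0], tract_len_range[1] + 1))
            k_mm = int(rng.choice(3, p=mw))
            if cursor + tlen + 10 > L - 5:
                break
            start = cursor
            unit = _random_primitive_unit(u, rng)
            tract = (unit * (tlen // u + 2))[:tlen]
            tract = list(tract)
            if k_mm:
                # substitutions strictly inside, not adjacent to each other
                inner = rng.choice(np.arange(2, tlen - 2), size=k_mm,
                                   replace=False)
                for pos in inner:
                    orig = tract[pos]
                    tract[pos] = rng.choice([b for b in "ACGT" if b != orig])
            chars[start:start + tlen] = tract
            # break the repeat on both sides
            exp_left = unit[(-1) % u]
            exp_right = unit[tlen % u]
            if start > 0:
                chars[start - 1] = rng.choice([b for b in "ACGT"
                                               if b != exp_left])
            if start + tlen < L:
                chars[start + tlen] = rng.choice([b for b in "ACGT"
                                                  if b != exp_right])
            truth.append(dict(seq_id=sid, start=start + 1, end=start + tlen,
                              unit_len=u, canonical_motif=canonical_motif(unit),
                              tract_len=tlen, n_mismatches=k_mm))
            cursor = start + tlen + int(rng.integers(20, 60))
        records.append(SeqRecord(Seq("".join(chars)), id=sid, description=""))
    cols = ["seq_id", "start", "end", "unit_len", "canonical_motif",
            "tract_len", "n_mismatches"]
    return records, pd.DataFrame(truth, columns=cols)


# ---------------------------------------------------------------------------
# synthetic reference genome and hit table

def simulate_reference(genome: SimGenome, loci: pd.DataFrame,
                       rearrangements: Sequence[Mapping] = (),
                       bp_per_cm: float = 50_000.0,
                       decoy_fraction: float = 0.0,
                       nohit_fraction: float = 0.0,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference gene coordinates colinear with the map, plus a hit table.

    Each marker gets one reference gene at bp = 1 + pos_cm * bp_per_cm on
    the ancestral chromosome of its (first) group.  ``rearrangements`` is a
    list of dicts {group, lo_cm, hi_cm, dest_chrom, invert?} translocating
    (and optionally inverting) a map segment.  ``decoy_fraction`` of markers
    receive an extra wrong-chromosome hit with a worse bitscore;
    ``nohit_fraction`` receive no hit at all.  Returns (gene truth frame,
    hit-table frame in :data:`clovermap.io._HIT_COLS` layout).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    chroms = sorted(set(genome.chrom_of_group.values()))
    first = loci.sort_values("locus_id").groupby("marker_id", sort=True).head(1)

    genes, hits = [], []
    for rec in first.itertuples():
        chrom = genome.chrom_of_group[rec.group]
        bp = 1 + int(round(rec.pos_cm * bp_per_cm))
        for rr in rearrangements:
            if (rec.group == rr["group"]
                    and rr["lo_cm"] <= rec.pos_cm <= rr["hi_cm"]):
                chrom = rr["dest_chrom"]
                seg = rec.pos_cm - rr["lo_cm"]
                if rr.get("invert"):
                    seg = rr["hi_cm"] - rec.pos_cm
                # land beyond the recipient's colinear span
                span = 1 + int(round(genome.group_lengths_cm[rec.group]
                                     * bp_per_cm))
                bp = span + 100_000 + int(round(seg * bp_per_cm))
        if rng.random() < nohit_fraction:
            genes.append(dict(marker_id=rec.marker_id, chromosome=chrom,
                              bp=bp, hit=False))
            continue
        genes.append(dict(marker_id=rec.marker_id, chromosome=chrom,
                          bp=bp, hit=True))
        hits.append(dict(query_id=rec.marker_id,
                         reference_id=f"gene:{rec.marker_id}",
                         chromosome=chrom, start_bp=bp, end_bp=bp + 500,
                         evalue=1e-30, bitscore=200.0))
        if rng.random() < decoy_fraction:
            wrong = [c for c in chroms if c != chrom]
            dc = wrong[int(rng.integers(0, len(wrong)))]
            dbp = 1 + int(rng.integers(0, 5_000_000))
            hits.append(dict(query_id=rec.marker_id,
                             reference_id=f"decoy:{rec.marker_id}",
                             chromosome=dc, start_bp=dbp, end_bp=dbp + 500,
                             evalue=1e-15, bitscore=100.0))
    from .io import _HIT_COLS

    return (pd.DataFrame(genes),
            pd.DataFrame(hits, columns=_HIT_COLS))


def simulate_dataset(genome: SimGenome | None = None,
                     design: SimDesign | None = None,
                     seed: int = 0, **reference_kwargs
                     ) -> tuple[GenotypeTable, SimTruth]:
    """Convenience wrapper: genome + both parents' gametes + rendered table.

    When no genome is supplied, a regular 16-group layout sized to the
    design's locus count is built.
    """
    design = (design or SimDesign()).validate()
    rng = np.random.default_rng(seed)
    if genome is None:
        n_pairs = 8
        per_group = int(np.ceil(design.n_loci / (2 * n_pairs)))
        genome = SimGenome.regular(n_pairs=n_pairs,
                                   markers_per_group=max(per_group, 2),
                                   rng=rng)
        # trim surplus positions so capacity matches the design exactly
        surplus = 2 * n_pairs * per_group - design.n_loci
        groups = genome.groups
        gi = 0
        while surplus > 0:
            g = groups[gi % len(groups)]
            if len(genome.marker_positions[g]) > 2:
                genome.marker_positions[g] = genome.marker_positions[g][:-1]
                surplus -= 1
            gi += 1
    haplos = {p: simulate_gametes(genome, design, p, rng)
              for p in ("P1", "P2")}
    loci = assign_loci(genome, design, rng)
    table, truth = render_genotype_table(haplos, loci, design, genome, rng)
    if reference_kwargs:
        genes, hits = simulate_reference(genome, loci, rng=rng,
                                         **reference_kwargs)
        truth.reference = genes
        truth.hits = hits  # type: ignore[attr-defined]
    return table, truth
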