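"""Pipeline configuration: every analysis threshold with its default.

Defaults are the operating values of the study design this pipeline
emulates (a 188-progeny full-sib allotetraploid family genotyped with
EST-SSR markers): LOD 10 grouping, REC <= 0.4, goodness-of-fit jump 5.0,
5-cM LD grid with an r^2 > 0.5 report threshold, synteny blocks of >= 3
anchors within 10 cM / 500 kb, SSR tracts >= 15 nt with 90-300 bp
amplicons, and E-value cutoffs of 1e-20 (nucleotide) and 1e-10 (protein).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimSection:
    """Synthetic-data generator settings (see :mod:`clovermap.simulate`)."""

    n_homeolog_pairs: int = 8
    group_length_cm: float = 100.0
    markers_per_group: int = 14
    n_progeny: int = 188
    n_biparental: int = 424
    n_female: int = 789
    n_male: int = 584
    multi_locus_fraction: float = 0.3
    missing_rate: float = 0.05
    error_rate: float = 0.01
    n_distortion_loci: int = 3
    distortion_s: float = 0.5
    planted_ld: list = field(default_factory=list)  # [parent, gA, posA, gB, posB, dprime]
    bp_per_cm: float = 50_000.0
    n_transcripts: int = 200
    transcript_length: tuple = (300, 1200)


@dataclass
class PipelineConfig:
    """All thresholds, the seed, and input/output paths."""

    # grouping / ordering
    lod_group: float = 10.0
    rec_max: float = 0.4
    jump: float = 5.0
    lod_order_min: float = 1.0
    pair_min_n: int = 20
    min_informative_frac: float = 0.2
    suspect_fraction: float = 0.25
    alpha: float = 0.05
    # integration
    min_anchors: int = 3
    # LD scan
    ld_grid_cm: float = 5.0
    ld_r2_min: float = 0.5
    ld_min_n: int = 30
    # synteny
    synteny_min_anchors: int = 3
    synteny_map_win_cm: float = 10.0
    synteny_ref_win_kb: float = 500.0
    evalue_nucl: float = 1e-20
    evalue_prot: float = 1e-10
    # SSR mining
    ssr_min_len: int = 15
    ssr_max_mismatch: int = 2
    amplicon_min: int = 90
    amplicon_max: int = 300
    min_flank: int = 20
    # misc
    seed: int = 0
    simulate: bool = True  # when False a genotype_table path is required
    genotype_table: str | None = None
    fasta: str | None = None
    hit_table: str | None = None
    outdir: str = "clovermap_out"
    sim: SimSection = field(default_factory=SimSection)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["transcript_length"] = list(d["sim"]["transcript_length"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, SimSection):
            sim_obj = sim
        else:
            sim = dict(sim)
            if "transcript_length" in sim:
                sim["transcript_length"] = tuple(sim["transcript_length"])
            sim_obj = SimSection(**sim)
        return cls(sim=sim_obj, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
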