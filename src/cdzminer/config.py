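"""Run configuration for the Cdz-like system miner.

Every tunable of the discovery procedure is collected here in flat
dataclasses so a whole run is reproducible from one YAML file plus one
integer seed.  Defaults encode the published search protocol: 10 kb
anchor flanks, candidate ORFs of 60-200 residues (translation table 11),
a two-iteration profile-HMM search, and the four-part glycine-zipper
toxin classifier (length 60-151, G[G/A/S] leader, one or two
uninterrupted zippers, short charged/polar tail).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: Residues regarded as charged (histidine is treated as polar, not charged).
CHARGED = frozenset("DEKR")
#: Polar, uncharged residues.
POLAR = frozenset("STNQHY")
#: Small hydrophobic residues that dominate the mature toxins.
SMALL_HYDROPHOBIC = frozenset("GAVI")
#: Zipper anchor residues (strict glycine by default).
ZIPPER_ANCHOR = frozenset("G")
#: Residues that may not occur between zipper anchors.
FORBIDDEN_IN_ZIPPER = frozenset(CHARGED | {"P", "C"})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ResidueClasses:
    """Residue partitions used by the rule-based toxin classifier."""

    charged: frozenset = CHARGED
    polar: frozenset = POLAR
    small_hydrophobic: frozenset = SMALL_HYDROPHOBIC
    zipper_anchor: frozenset = ZIPPER_ANCHOR
    forbidden_in_zipper: frozenset = FORBIDDEN_IN_ZIPPER

    def __post_init__(self) -> None:
        self.charged = frozenset(self.charged)
        self.polar = frozenset(self.polar)
        self.small_hydrophobic = frozenset(self.small_hydrophobic)
        self.zipper_anchor = frozenset(self.zipper_anchor)
        self.forbidden_in_zipper = frozenset(self.forbidden_in_zipper)
        if self.zipper_anchor & self.forbidden_in_zipper:
            raise ValueError("zipper anchors cannot also be forbidden in zippers")


@dataclass
class OrfParams:
    """Bounds and codon conventions of the six-frame ORF scan."""

    min_res: int = 60
    max_res: int = 200
    start_codons: tuple = ("ATG", "GTG", "TTG")
    all_starts: bool = True
    table: int = 11

    def __post_init__(self) -> None:
        if not (0 < self.min_res <= self.max_res):
            raise ValueError("require 0 < min_res <= max_res")
        self.start_codons = tuple(str(c).upper() for c in self.start_codons)


@dataclass
class ClassifierParams:
    """Thresholds of the four-part toxin classifier.

    The length band (full ORF, 60-151 aa) and the G[G/A/S] leader rule
    are the published criteria; the numeric windows (leader 10-35,
    flank window 3, polar-span window 6 with >4 charged/polar, tail
    <=20 with >=0.4 charged/polar) parameterise the prose criteria and
    are exposed for sensitivity analyses.
    """

    min_len: int = 60
    max_len: int = 151
    min_leader: int = 10
    max_leader: int = 35
    min_anchors: int = 3
    max_motifs: int = 2
    flank_window: int = 3
    require_flank: bool = True
    max_tail: int = 20
    min_charged_polar_frac: float = 0.4
    polar_span_window: int = 6
    polar_span_max: int = 4
    classes: ResidueClasses = field(default_factory=ResidueClasses)


@dataclass
class HmmParams:
    """Profile construction and score-calibration settings."""

    gap_threshold: float = 0.5
    pseudocount_weight: float = 1.0
    n_random: int = 200
    alpha: float = 1e-3
    calibration_seed: int = 77


@dataclass
class PipelineParams:
    """Genomic-context search settings."""

    flank_nt: int = 10_000
    n_iter: int = 2
    anchor_group_nt: int = 5_000
    adjacency_gap_nt: int = 500
    anchor_min_res: int = 200
    anchor_max_res: int = 900
    require_anchor_context: bool = True


@dataclass
class MinerConfig:
    """Top-level configuration: one object drives a full scan."""

    seed: int = 1
    orf: OrfParams = field(default_factory=OrfParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    hmm: HmmParams = field(default_factory=HmmParams)
    pipeline: PipelineParams = field(default_factory=PipelineParams)

    def to_dict(self) -> dict:
        def conv(o):
            if dataclasses.is_dataclass(o):
                return {f.name: conv(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            if isinstance(o, (tuple, list)):
                return [conv(v) for v in o]
            return o

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "MinerConfig":
        kw = {}
        sub = {
            "orf": OrfParams,
            "classifier": ClassifierParams,
            "hmm": HmmParams,
            "pipeline": PipelineParams,
        }
        for key, val in d.items():
            if key in sub:
                payload = dict(val)
                if key == "classifier" and "classes" in payload:
                    payload["classes"] = ResidueClasses(
                        **{k: frozenset(v) for k, v in payload["classes"].items()}
                    )
                kw[key] = sub[key](**payload)
            else:
                kw[key] = val
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "MinerConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
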