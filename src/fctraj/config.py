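"""Analysis configuration: domain/loop definitions and all tunable criteria.

Every threshold used by the analyses lives here with its conventional
default — 0.25 nm / 135 deg hydrogen-bond criteria, 0.14 nm probe radius,
1.4 nm long-range cutoff for the periodicity check, 2 ps frame subsampling,
backbone C/CA/N fit atoms, and the engineered C-terminal loop ranges
AB 358-362, CD 383-391, EF 413-422 (Eu numbering).  Configurations
round-trip through YAML.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .hbond import HBondCriteria
from .model import SelectionSpec

__all__ = [
    "OrientationDescriptor",
    "AnalysisConfig",
    "DEFAULT_LOOP_RANGES",
    "default_domain_definitions",
    "default_descriptors",
]

#: Engineered C-terminal loop ranges (Eu numbering), inclusive.
DEFAULT_LOOP_RANGES = {"AB": (358, 362), "CD": (383, 391), "EF": (413, 422)}

ALL_ANALYSES = (
    "rmsd", "rmsf", "rgyr", "hbond", "dihedrals", "orientation",
    "periodicity", "sasa",
)


@dataclass(frozen=True)
class OrientationDescriptor:
    """One inter-domain orientation descriptor: the angle between two domain
    axes, or their torsion about the inter-center line."""

    label: str
    kind: str  # "angle" or "dihedral"
    domain1: str
    domain2: str

    def __post_init__(self) -> None:
        if self.kind not in ("angle", "dihedral"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")


def default_domain_definitions() -> dict[str, SelectionSpec]:
    """CH2/CH3 core domains of a two-chain Fc-like construct.

    Residue ranges are Eu-flavoured: CH2 in the 238-340 span, CH3 in
    341-444.  Loop ranges are excluded from the domain cores used for
    fitting and axis computation.
    """
    defs = {}
    for chain in ("A", "B"):
        defs[f"CH2{chain}"] = SelectionSpec.make(
            chain_ids={chain}, residue_ranges=[(238, 340)],
            segment_classes={"protein"},
        )
        defs[f"CH3{chain}"] = SelectionSpec.make(
            chain_ids={chain}, residue_ranges=[(341, 357)],
            segment_classes={"protein"},
        )
        for loop, (lo, hi) in DEFAULT_LOOP_RANGES.items():
            defs[f"loop{loop}{chain}"] = SelectionSpec.make(
                chain_ids={chain}, residue_ranges=[(lo, hi)],
                segment_classes={"protein"},
            )
    return defs


def default_descriptors() -> list[OrientationDescriptor]:
    """The eight standard descriptors A-H for a CH2/CH3 two-chain system."""
    return [
        OrientationDescriptor("A", "angle", "CH2A", "CH3A"),
        OrientationDescriptor("B", "angle", "CH2B", "CH3B"),
        OrientationDescriptor("C", "angle", "CH2A", "CH2B"),
        OrientationDescriptor("D", "angle", "CH3A", "CH3B"),
        OrientationDescriptor("E", "dihedral", "CH2A", "CH3A"),
        OrientationDescriptor("F", "dihedral", "CH2B", "CH3B"),
        OrientationDescriptor("G", "dihedral", "CH2A", "CH2B"),
        OrientationDescriptor("H", "dihedral", "CH3A", "CH3B"),
    ]


@dataclass
class AnalysisConfig:
    """Everything the analysis pipeline needs beyond the input files."""

    domain_definitions: dict[str, SelectionSpec] = field(
        default_factory=default_domain_definitions)
    descriptors: list[OrientationDescriptor] = field(
        default_factory=default_descriptors)
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    hbond_donor_sel: SelectionSpec = field(
        default_factory=lambda: SelectionSpec.make(segment_classes={"protein"}))
    hbond_acceptor_sel: SelectionSpec = field(
        default_factory=lambda: SelectionSpec.make(segment_classes={"protein"}))
    sasa_probe_radius: float = 0.14
    sasa_sphere_points: int = 960
    sasa_hydrogen_radius: float = 0.0
    periodicity_cutoff: float = 1.4
    fit_atom_names: frozenset[str] = frozenset({"C", "CA", "N"})
    subsample_interval: float = 2.0
    loop_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LOOP_RANGES))
    analyses: tuple[str, ...] = ALL_ANALYSES

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def sel_dict(s: SelectionSpec) -> dict:
            d = {}
            if s.chain_ids is not None:
                d["chain_ids"] = sorted(s.chain_ids)
            if s.residue_ranges is not None:
                d["residue_ranges"] = [list(r) for r in s.residue_ranges]
            if s.atom_names is not None:
                d["atom_names"] = sorted(s.atom_names)
            if s.segment_classes is not None:
                d["segment_classes"] = sorted(c.value for c in s.segment_classes)
            return d

        return {
            "domain_definitions": {k: sel_dict(v)
                                   for k, v in self.domain_definitions.items()},
            "descriptors": [
                {"label": d.label, "kind": d.kind,
                 "domain1": d.domain1, "domain2": d.domain2}
                for d in self.descriptors
            ],
            "hbond_criteria": {
                "max_h_acceptor_distance": self.hbond_criteria.max_h_acceptor_distance,
                "min_dha_angle": self.hbond_criteria.min_dha_angle,
            },
            "hbond_donor_sel": sel_dict(self.hbond_donor_sel),
            "hbond_acceptor_sel": sel_dict(self.hbond_acceptor_sel),
            "sasa_probe_radius": self.sasa_probe_radius,
            "sasa_sphere_points": self.sasa_sphere_points,
            "sasa_hydrogen_radius": self.sasa_hydrogen_radius,
            "periodicity_cutoff": self.periodicity_cutoff,
            "fit_atom_names": sorted(self.fit_atom_names),
            "subsample_interval": self.subsample_interval,
            "loop_ranges": {k: list(v) for k, v in self.loop_ranges.items()},
            "analyses": list(self.analyses),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        def sel(d: Optional[dict]) -> SelectionSpec:
            d = d or {}
            return SelectionSpec.make(
                chain_ids=d.get("chain_ids"),
                residue_ranges=d.get("residue_ranges"),
                atom_names=d.get("atom_names"),
                segment_classes=d.get("segment_classes"),
            )

        kwargs: dict = {}
        if "domain_definitions" in data:
            kwargs["domain_definitions"] = {
                k: sel(v) for k, v in data["domain_definitions"].items()
            }
        if "descriptors" in data:
            kwargs["descriptors"] = [
                OrientationDescriptor(**d) for d in data["descriptors"]
            ]
        if "hbond_criteria" in data:
            kwargs["hbond_criteria"] = HBondCriteria(**data["hbond_criteria"])
        for key in ("hbond_donor_sel", "hbond_acceptor_sel"):
            if key in data:
                kwargs[key] = sel(data[key])
        for key in ("sasa_probe_radius", "sasa_sphere_points",
                    "sasa_hydrogen_radius", "periodicity_cutoff",
                    "subsample_interval"):
            if key in data:
                kwargs[key] = data[key]
        if "fit_atom_names" in data:
            kwargs["fit_atom_names"] = frozenset(data["fit_atom_names"])
        if "loop_ranges" in data:
            kwargs["loop_ranges"] = {
                k: tuple(v) for k, v in data["loop_ranges"].items()
            }
        if "analyses" in data:
            kwargs["analyses"] = tuple(data["analyses"])
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
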