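"""Configuration-driven analysis pipeline and report writers.

Runs every enabled analysis on a structure + trajectory and writes
TSV reports shaped like the field's customary tables and figures: per-domain
RMSD series, per-residue RMSF, radius-of-gyration series, a from/to
hydrogen-bond prevalence matrix, a per-residue H-bond/SASA profile, a
dihedral-transition table, the eight orientation-descriptor series, a
periodic-contact log and a loop-SASA summary.  Reruns with identical inputs
produce byte-identical output files.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fitting, geometry, hbond
from .sasa import group_area, interface_area
from .sasa import sasa as compute_sasa
from .config import AnalysisConfig
from .dihedrals import count_transitions, dihedral_series
from .io import read_structure, read_torsion_table, read_trajectory
from .model import (
    SegmentClass,
    SelectionSpec,
    StructureModel,
    Trajectory,
    resolve_selection,
    subsample,
)

__all__ = ["PipelineReport", "run_pipeline", "analyze_files"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"


@dataclass
class PipelineReport:
    """All tables produced by one pipeline run, plus the run manifest."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir) -> list[str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        try:
            for name, df in self.tables.items():
                path = out / f"{name}.tsv"
                df.to_csv(path, sep="\t", index=False,
                          float_format=_FLOAT_FMT)
                written.append(str(path))
            manifest_path = out / "manifest.json"
            manifest_path.write_text(
                json.dumps(self.manifest, indent=1, sort_keys=True))
            written.append(str(manifest_path))
        except Exception:
            for p in written:
                Path(p).unlink(missing_ok=True)
            raise
        return written


def _protein_sel() -> SelectionSpec:
    return SelectionSpec.make(segment_classes={"protein"})


def _solute_sel() -> SelectionSpec:
    return SelectionSpec.make(segment_classes={"protein", "glycan"})


def _backbone_ids(model: StructureModel, base: SelectionSpec,
                  fit_atom_names: frozenset[str]) -> list[int]:
    ids = resolve_selection(model, base)
    return [i for i in ids if model.atom(i).atom_name in fit_atom_names]


def _core_domains(config: AnalysisConfig) -> list[str]:
    return [d for d in config.domain_definitions if not d.startswith("loop")]


def _rmsd_table(traj, model, config) -> pd.DataFrame:
    data = {"time_ps": traj.times()}
    for label in _core_domains(config):
        sel = _backbone_ids(model, config.domain_definitions[label],
                            config.fit_atom_names)
        if not sel:
            logger.warning("domain %s selects no backbone atoms; skipped", label)
            continue
        data[label] = fitting.rmsd_series(traj, model, sel, sel)
    return pd.DataFrame(data)


def _rmsf_table(traj, model, config) -> pd.DataFrame:
    fit_sel = []
    for label in _core_domains(config):
        fit_sel += _backbone_ids(model, config.domain_definitions[label],
                                 config.fit_atom_names)
    calc_sel = _backbone_ids(model, _protein_sel(), config.fit_atom_names)
    values = fitting.rmsf(traj, model, fit_sel, calc_sel)
    rows = {}
    for atom_id, v in zip(calc_sel, values):
        a = model.atom(atom_id)
        rows.setdefault((a.chain_id, a.residue_number), []).append(v)
    return pd.DataFrame([
        {"chain": c, "residue": r, "rmsf_nm": float(np.mean(vs))}
        for (c, r), vs in sorted(rows.items())
    ])


def _rgyr_table(traj, model, config) -> pd.DataFrame:
    groups: dict[str, list[int]] = {
        "system": resolve_selection(model, _solute_sel()),
    }
    for label in _core_domains(config):
        groups[label] = resolve_selection(model, config.domain_definitions[label])
    for chain in sorted({a.chain_id for a in model.atoms}):
        sel = resolve_selection(model, SelectionSpec.make(
            chain_ids={chain}, segment_classes={"glycan"}))
        if sel:
            groups[f"glycan{chain}"] = sel
    data = {"time_ps": traj.times()}
    for name, sel in groups.items():
        if not sel:
            continue
        data[name] = [
            fitting.radius_of_gyration(model, fr, sel) for fr in traj
        ]
    return pd.DataFrame(data)


def _hbond_tables(traj, model, config) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    triplets = hbond.candidate_triplets(
        model, config.hbond_donor_sel, config.hbond_acceptor_sel)
    records = hbond.prevalence(traj, model, triplets, config.hbond_criteria)

    chains = sorted({a.chain_id for a in model.atoms
                     if a.segment_class == SegmentClass.PROTEIN})
    groups = {f"chain{c}": SelectionSpec.make(chain_ids={c}) for c in chains}
    rows = []
    for i, (from_label, from_sel) in enumerate(groups.items()):
        for to_label, to_sel in list(groups.items())[i:]:
            rows.append({
                "from": from_label, "to": to_label,
                "summed_prevalence_pct": hbond.aggregate(
                    records, model, from_sel, to_sel),
            })
    matrix = pd.DataFrame(rows)

    # per-residue mean H-bond counts, inter-chain fraction separated
    chain_of = {a.atom_id: a.chain_id for a in model.atoms}
    res_of = {a.atom_id: (a.chain_id, a.residue_number) for a in model.atoms}
    per_res: dict[tuple[str, int], dict[str, float]] = {}
    for rec in records:
        inter = chain_of[rec.donor_id] != chain_of[rec.acceptor_id]
        for atom_id in {rec.donor_id, rec.acceptor_id}:
            key = res_of[atom_id]
            d = per_res.setdefault(key, {"total": 0.0, "interchain": 0.0})
            d["total"] += rec.prevalence / 100.0
            if inter:
                d["interchain"] += rec.prevalence / 100.0
    residue_table = pd.DataFrame([
        {"chain": c, "residue": r, "mean_hbonds": v["total"],
         "mean_interchain_hbonds": v["interchain"]}
        for (c, r), v in sorted(per_res.items())
    ])
    return matrix, residue_table, records


def _transitions_table(traj, model, terms) -> pd.DataFrame:
    rows = []
    for k, term in enumerate(terms, start=1):
        series = dihedral_series(traj, model, term)
        atoms = [model.atom(i) for i in term.atom_ids]
        gl = [a.glycan_index for a in atoms if a.glycan_index is not None]
        pair = f"{min(gl)}-{max(gl)}" if gl else ""
        rows.append({
            "dihedral": k,
            "atoms": "-".join(a.atom_name for a in atoms),
            "residue_pair": pair,
            "chain": atoms[0].chain_id,
            "transitions": count_transitions(series),
        })
    return pd.DataFrame(rows)


def _orientation_table(traj, model, config) -> pd.DataFrame:
    needed = {d for desc in config.descriptors
              for d in (desc.domain1, desc.domain2)}
    axes: dict[str, list[np.ndarray]] = {d: [] for d in needed}
    centers: dict[str, list[np.ndarray]] = {d: [] for d in needed}
    for domain in needed:
        sel = resolve_selection(model, config.domain_definitions[domain])
        prev = None
        for fr in traj:
            axis = geometry.principal_axis(fr, model, sel, prev_axis=prev)
            axes[domain].append(axis)
            centers[domain].append(geometry.center_of_geometry(fr, model, sel))
            prev = axis
    data = {"time_ps": traj.times()}
    for desc in config.descriptors:
        vals = []
        for t in range(len(traj)):
            a1 = axes[desc.domain1][t]
            a2 = axes[desc.domain2][t]
            if desc.kind == "angle":
                vals.append(geometry.interdomain_angle(a1, a2))
            else:
                vals.append(geometry.interdomain_dihedral(
                    a1, centers[desc.domain1][t],
                    centers[desc.domain2][t], a2))
        data[desc.label] = vals
    return pd.DataFrame(data)


def _periodicity_table(traj, model, config) -> pd.DataFrame:
    solute = resolve_selection(model, _solute_sel())
    rows = []
    for fr in traj:
        if fr.box is None:
            # vacuum frames carry no periodicity; skip rather than fail
            continue
        res = geometry.periodic_contact(fr, model, solute,
                                        config.periodicity_cutoff)
        rows.append({"time_ps": fr.time,
                     "min_image_distance_nm": res["min_image_distance"],
                     "contact": int(res["flag"])})
    return pd.DataFrame(rows, columns=["time_ps", "min_image_distance_nm",
                                       "contact"])


def _sasa_tables(traj, model, config) -> tuple[pd.DataFrame, pd.DataFrame]:
    protein = resolve_selection(model, _protein_sel())
    chains = sorted({a.chain_id for a in model.atoms
                     if a.segment_class == SegmentClass.PROTEIN})
    kwargs = dict(probe=config.sasa_probe_radius,
                  n_points=config.sasa_sphere_points,
                  hydrogen_radius=config.sasa_hydrogen_radius)
    per_res_area: dict[tuple[str, int], list[float]] = {}
    per_res_buried: dict[tuple[str, int], list[float]] = {}
    loop_areas: dict[str, list[float]] = {}
    for fr in traj:
        result = compute_sasa(fr, model, protein, **kwargs)
        buried = None
        if len(chains) == 2:
            selA = resolve_selection(model, SelectionSpec.make(
                chain_ids={chains[0]}, segment_classes={"protein"}))
            selB = resolve_selection(model, SelectionSpec.make(
                chain_ids={chains[1]}, segment_classes={"protein"}))
            buried = interface_area(fr, model, selA, selB, **kwargs)
        frame_res_area: dict[tuple[str, int], float] = {}
        frame_res_buried: dict[tuple[str, int], float] = {}
        for atom_id, area in result.per_atom_area.items():
            a = model.atom(atom_id)
            key = (a.chain_id, a.residue_number)
            frame_res_area[key] = frame_res_area.get(key, 0.0) + area
            if buried is not None:
                frame_res_buried[key] = (
                    frame_res_buried.get(key, 0.0)
                    + buried["per_atom_buried"].get(atom_id, 0.0))
        for key, v in frame_res_area.items():
            per_res_area.setdefault(key, []).append(v)
        for key, v in frame_res_buried.items():
            per_res_buried.setdefault(key, []).append(v)
        for loop, (lo, hi) in config.loop_ranges.items():
            for chain in chains:
                spec = SelectionSpec.make(chain_ids={chain},
                                          residue_ranges=[(lo, hi)],
                                          segment_classes={"protein"})
                label = f"{loop}{chain}"
                loop_areas.setdefault(label, []).append(
                    group_area(result, model, spec))

    residue_profile = pd.DataFrame([
        {"chain": c, "residue": r,
         "mean_sasa_nm2": float(np.mean(vs)),
         "mean_interface_nm2": float(np.mean(
             per_res_buried.get((c, r), [0.0])))}
        for (c, r), vs in sorted(per_res_area.items())
    ])
    # loop surface accounting: per-chain sum over the three loops
    rows = []
    for label, vs in sorted(loop_areas.items()):
        rows.append({"loops": label, "mean_nm2": float(np.mean(vs)),
                     "sd_nm2": float(np.std(vs))})
    for chain in chains:
        per_frame = np.sum(
            [loop_areas[f"{loop}{chain}"] for loop in config.loop_ranges],
            axis=0)
        rows.append({"loops": f"all_{chain}",
                     "mean_nm2": float(np.mean(per_frame)),
                     "sd_nm2": float(np.std(per_frame))})
    return residue_profile, pd.DataFrame(rows)


def run_pipeline(model: StructureModel, traj: Trajectory,
                 config: AnalysisConfig,
                 out_dir: Optional[str] = None,
                 manifest_extra: Optional[dict] = None) -> PipelineReport:
    """Run all enabled analyses on a 2 ps-subsampled trajectory.

    Validation (e.g. torsion terms present when the dihedral analysis is
    enabled) happens before any computation; disabling one analysis never
    changes the outputs of the others.
    """
    analyses = set(config.analyses)
    if "dihedrals" in analyses and not model.torsion_terms:
        raise ValueError(
            "dihedral analysis enabled but no torsion terms supplied")

    work = subsample(traj, config.subsample_interval)
    report = PipelineReport()
    report.manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "n_frames_analyzed": len(work),
        "subsample_interval_ps": config.subsample_interval,
        **(manifest_extra or {}),
    }
    if "rmsd" in analyses:
        report.tables["rmsd"] = _rmsd_table(work, model, config)
    if "rmsf" in analyses:
        report.tables["fig2_rmsf"] = _rmsf_table(work, model, config)
    if "rgyr" in analyses:
        report.tables["rgyr"] = _rgyr_table(work, model, config)
    if "hbond" in analyses:
        matrix, residues, _ = _hbond_tables(work, model, config)
        report.tables["table2_hbonds"] = matrix
        report.tables["fig4_residue_hbonds"] = residues
    if "dihedrals" in analyses:
        report.tables["table1_transitions"] = _transitions_table(
            work, model, model.torsion_terms)
    if "orientation" in analyses:
        report.tables["fig3_orientation"] = _orientation_table(
            work, model, config)
    if "periodicity" in analyses:
        report.tables["periodic_contacts"] = _periodicity_table(
            work, model, config)
    if "sasa" in analyses:
        profile, loops = _sasa_tables(work, model, config)
        report.tables["fig4_residue_profile"] = profile
        report.tables["loops_sasa"] = loops
    if out_dir is not None:
        report.write(out_dir)
    return report


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_files(structure_path, trajectory_path, config_path=None,
                  torsion_path=None, out_dir=None,
                  frame_spacing: float = 2.0) -> PipelineReport:
    """File-level entry point: read inputs, run the pipeline, write reports."""
    config = (AnalysisConfig.load(config_path) if config_path
              else AnalysisConfig())
    if "dihedrals" in config.analyses and torsion_path is None:
        raise ValueError(
            "dihedral analysis enabled but no torsion table given")
    model = read_structure(structure_path)
    if torsion_path is not None:
        terms = read_torsion_table(torsion_path)
        model = StructureModel(model.atoms, model.bonds, terms)
    traj = read_trajectory(trajectory_path, model=model,
                           frame_spacing=frame_spacing)
    extra = {"structure_sha256": _sha256(structure_path),
             "trajectory_sha256": _sha256(trajectory_path)}
    if torsion_path is not None:
        extra["torsions_sha256"] = _sha256(torsion_path)
    return run_pipeline(model, traj, config, out_dir=out_dir,
                        manifest_extra=extra)
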