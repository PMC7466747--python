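"""End-to-end assignment pipeline, report serialization and restraints.

``run_pipeline`` drives the whole analysis: detect the dinucleotide steps of
a coordinate file, measure the 12 parameters of each, assign NtC/CANA
classes, score confals, profile similarity against every class and measure
the connectivity of neighboring assignments.  Reports serialize to CSV (the
per-step table) or JSON (the full data model, round-trippable); assigned
steps can further be turned into torsion restraints for refinement or into
an mmCIF file of superposed reference conformers.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .classify import Assignment, DistanceProfile, NtCClassifier
from .confal import ConfalBreakdown, confal_breakdown, structure_confal, structure_percentile
from .diagnostics import ConnectivityReport, connectivity, rmsd_band, similarity_profile
from .geometry import PARAMETER_NAMES, TORSION_ATOMS, TORSION_NAMES, StepParameters, \
    compute_step_parameters, superpose_rmsd
from .reference import ReferenceSet, UNASSIGNED_CANA, UNASSIGNED_NTC
from .structure_io import ATOM_ROLES, AtomRecord, DinucleotideStep, ResidueRef, \
    detect_steps, read_structure

logger = logging.getLogger("ntckit")

__all__ = [
    "PipelineConfig",
    "StepRecord",
    "StructureReport",
    "RestraintEdit",
    "run_pipeline",
    "write_report",
    "read_report",
    "write_restraints",
    "write_superposed_references",
]

#: default Cartesian r.m.s.d. cutoff for emitting restraints (A)
DEFAULT_RESTRAINT_RMSD_CUTOFF = 1.0


@dataclass
class PipelineConfig:
    """Tunable knobs of the assignment pipeline."""

    k: int | None = None            # None: 1 for class-means training, 11 otherwise
    cutoff: float | None = 4.5      # rejection cutoff in scaled units
    scaling: np.ndarray | None = None  # None: class-pooled e.s.d.
    linkage_cutoff: float = 2.5     # O3'(1)-P(2) consecutiveness (A)
    model: int | None = None        # None: analyze every model
    min_occupancy: float | None = None
    training: tuple | None = None   # optional (X, y) labeled training vectors


@dataclass
class StepRecord:
    """Everything the pipeline knows about one detected step."""

    step: DinucleotideStep
    parameters: StepParameters
    assignment: Assignment
    band: str | None = None
    connectivity: ConnectivityReport = field(default_factory=ConnectivityReport)

    @property
    def name(self) -> str:
        return self.step.step_name


@dataclass
class StructureReport:
    """Ordered assignments plus structure-level summary."""

    source: str
    refset_version: str
    steps: list = field(default_factory=list)
    structure_confal: float | None = None
    percentile: float | None = None
    counts: dict = field(default_factory=lambda: {"green": 0, "yellow": 0, "red": 0})
    n_unassigned: int = 0
    cana_strings: dict = field(default_factory=dict)  # "model/chain" -> list of symbols

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def n_assigned(self) -> int:
        return self.n_steps - self.n_unassigned

    @property
    def fraction_unassigned(self) -> float:
        return self.n_unassigned / self.n_steps if self.steps else 0.0


@dataclass(frozen=True)
class RestraintEdit:
    """Manual override of the class targeted by the restraints of one step."""

    step_name: str
    target_ntc: str


def run_pipeline(coords, refset: ReferenceSet,
                 config: PipelineConfig | None = None,
                 score_distribution=None) -> StructureReport:
    """Assign, score and diagnose every detectable step of a structure.

    ``coords`` is a file path (mmCIF/PDB) or an already-parsed gemmi
    structure.  Deterministic for fixed inputs and configuration.
    """
    config = config or PipelineConfig()
    structure = coords if isinstance(coords, gemmi.Structure) else read_structure(coords)
    clf = NtCClassifier.from_reference(refset, training=config.training,
                                       k=config.k, cutoff=config.cutoff,
                                       scaling=config.scaling)
    model_nos = [m.num for m in structure]
    if config.model is not None:
        model_nos = [config.model]

    records: list[StepRecord] = []
    for model_no in model_nos:
        steps = detect_steps(structure, model_no=model_no,
                             linkage_cutoff=config.linkage_cutoff,
                             min_occupancy=config.min_occupancy)
        logger.info("model %d: %d steps detected", model_no, len(steps))
        for step in steps:
            params = compute_step_parameters(step)
            label, nn, votes = clf.predict_detail(params.as_array())[0]
            profile = similarity_profile(step, params, refset, scaling=clf.scaling_)
            assignment = Assignment(
                step_name=step.step_name, ntc=str(label),
                cana=refset.cana_of(str(label)),
                nn_distance=nn, votes=votes, distance_profile=profile)
            record = StepRecord(step=step, parameters=params, assignment=assignment)
            if assignment.assigned:
                cls = refset.get(assignment.ntc)
                assignment.confal = confal_breakdown(params, cls)
                if assignment.ntc in profile.rmsd:
                    assignment.rmsd_to_assigned = profile.rmsd[assignment.ntc]
                    record.band = rmsd_band(assignment.rmsd_to_assigned)
            records.append(record)

    _fill_connectivity(records, refset)
    return _summarize(structure.name, refset, records, score_distribution)


def _adjacent(a: StepRecord, b: StepRecord) -> bool:
    return (a.step.first.model_no == b.step.first.model_no
            and a.step.second.chain_id == b.step.first.chain_id
            and a.step.second.res_seq == b.step.first.res_seq
            and a.step.second.ins_code == b.step.first.ins_code
            and a.step.second.altloc == b.step.first.altloc)


def _fill_connectivity(records, refset):
    for a, b in zip(records, records[1:]):
        if not (_adjacent(a, b) and a.assignment.assigned and b.assignment.assigned):
            continue
        try:
            ov = connectivity(a.step, a.assignment.ntc, b.step, b.assignment.ntc, refset)
        except (ValueError, KeyError):
            continue
        a.connectivity.next_C5 = ov.c5
        a.connectivity.next_O3 = ov.o3
        b.connectivity.prev_C5 = ov.c5
        b.connectivity.prev_O3 = ov.o3


def _summarize(source, refset, records, score_distribution) -> StructureReport:
    report = StructureReport(source=source, refset_version=refset.version, steps=records)
    scores = []
    for rec in records:
        a = rec.assignment
        chain_key = f"{rec.step.first.model_no}/{rec.step.first.chain_id}"
        report.cana_strings.setdefault(chain_key, []).append(a.cana)
        if not a.assigned:
            report.n_unassigned += 1
            continue
        if rec.band is not None:
            report.counts[rec.band] += 1
        if a.confal is not None:
            scores.append(a.confal.step_score)
    if scores:
        report.structure_confal = structure_confal(scores)
        if score_distribution is not None:
            report.percentile = structure_percentile(report.structure_confal,
                                                     score_distribution)
    return report


# ---------------------------------------------------------------------------
# serialization

_CSV_COLUMNS = ["step_name", "CANA", "NtC", "confal", "rmsd"] + \
    list(PARAMETER_NAMES) + ["band"]


def _csv_text(report: StructureReport) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_CSV_COLUMNS)
    for rec in report.steps:
        a = rec.assignment
        confal = "" if a.confal is None else f"{a.confal.step_score:.0f}"
        rmsd = "" if a.rmsd_to_assigned is None else f"{a.rmsd_to_assigned:.3f}"
        row = [rec.name, a.cana, a.ntc, confal, rmsd]
        row += [f"{v:.2f}" for v in rec.parameters.as_array()]
        row.append(rec.band or "")
        w.writerow(row)
    return buf.getvalue()


def _residue_dict(ref: ResidueRef) -> dict:
    return {"model_no": ref.model_no, "chain_id": ref.chain_id,
            "res_name": ref.res_name, "res_seq": ref.res_seq,
            "ins_code": ref.ins_code, "altloc": ref.altloc}


def _step_dict(rec: StepRecord) -> dict:
    a = rec.assignment
    atoms = []
    for (idx, role) in ATOM_ROLES:
        atom = rec.step.atoms[(idx, role)]
        atoms.append({"residue": idx, "role": role, "name": atom.name,
                      "element": atom.element, "altloc": atom.altloc,
                      "occupancy": round(atom.occupancy, 4),
                      "xyz": [round(v, 6) for v in atom.xyz]})
    d = {
        "step_name": rec.name,
        "first": _residue_dict(rec.step.first),
        "second": _residue_dict(rec.step.second),
        "parameters": {n: round(v, 6) for n, v in
                       zip(PARAMETER_NAMES, rec.parameters.as_array())},
        "ntc": a.ntc,
        "cana": a.cana,
        "nn_distance": round(a.nn_distance, 6),
        "rmsd": None if a.rmsd_to_assigned is None else round(a.rmsd_to_assigned, 6),
        "band": rec.band,
        "confal": None,
        "profile": None,
        "connectivity": {k: (None if v is None else round(v, 6))
                         for k, v in vars(rec.connectivity).items()},
        "atoms": atoms,
    }
    if a.confal is not None:
        d["confal"] = {
            "step_score": round(a.confal.step_score, 6),
            "per_parameter": {n: round(v, 6) for n, v in
                              zip(PARAMETER_NAMES, a.confal.per_parameter)},
            "deviations": {n: round(v, 6) for n, v in
                           zip(PARAMETER_NAMES, a.confal.deviations)},
        }
    if a.distance_profile is not None:
        d["profile"] = {
            "euclid": {c: round(v, 6) for c, v in sorted(a.distance_profile.euclid.items())},
            "rmsd": {c: round(v, 6) for c, v in sorted(a.distance_profile.rmsd.items())},
        }
    return d


def _json_text(report: StructureReport) -> str:
    doc = {
        "source": report.source,
        "refset_version": report.refset_version,
        "n_steps": report.n_steps,
        "n_unassigned": report.n_unassigned,
        "fraction_unassigned": round(report.fraction_unassigned, 6),
        "structure_confal": None if report.structure_confal is None
        else round(report.structure_confal, 6),
        "percentile": None if report.percentile is None else round(report.percentile, 6),
        "counts": report.counts,
        "cana_strings": {k: "-".join(v) for k, v in sorted(report.cana_strings.items())},
        "steps": [_step_dict(rec) for rec in report.steps],
    }
    return json.dumps(doc, indent=2, sort_keys=False) + "\n"


def write_report(report: StructureReport, path, format: str = "csv") -> Path:
    """Write a report as CSV (per-step table) or JSON (full data model)."""
    path = Path(path)
    if format == "csv":
        path.write_text(_csv_text(report))
    elif format == "json":
        path.write_text(_json_text(report))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path) -> StructureReport:
    """Reconstruct a StructureReport from its JSON serialization."""
    doc = json.loads(Path(path).read_text())
    records = []
    for sd in doc["steps"]:
        atoms = {}
        for ad in sd["atoms"]:
            atoms[(ad["residue"], ad["role"])] = AtomRecord(
                name=ad["name"], element=ad["element"],
                xyz=np.array(ad["xyz"], dtype=float),
                altloc=ad["altloc"], occupancy=ad["occupancy"])
        step = DinucleotideStep(
            first=ResidueRef(**sd["first"]), second=ResidueRef(**sd["second"]),
            atoms=atoms, step_name=sd["step_name"])
        params = StepParameters(**sd["parameters"])
        assignment = Assignment(
            step_name=sd["step_name"], ntc=sd["ntc"], cana=sd["cana"],
            nn_distance=sd["nn_distance"], rmsd_to_assigned=sd["rmsd"])
        if sd.get("confal") is not None:
            assignment.confal = ConfalBreakdown(
                per_parameter=np.array([sd["confal"]["per_parameter"][n]
                                        for n in PARAMETER_NAMES]),
                step_score=sd["confal"]["step_score"],
                deviations=np.array([sd["confal"]["deviations"][n]
                                     for n in PARAMETER_NAMES]))
        if sd.get("profile") is not None:
            assignment.distance_profile = DistanceProfile(
                euclid=dict(sd["profile"]["euclid"]), rmsd=dict(sd["profile"]["rmsd"]))
        conn = ConnectivityReport(**sd["connectivity"])
        records.append(StepRecord(step=step, parameters=params,
                                  assignment=assignment, band=sd["band"],
                                  connectivity=conn))
    report = StructureReport(
        source=doc["source"], refset_version=doc["refset_version"], steps=records,
        structure_confal=doc["structure_confal"], percentile=doc["percentile"],
        counts=doc["counts"], n_unassigned=doc["n_unassigned"],
        cana_strings={k: v.split("-") if v else [] for k, v in doc["cana_strings"].items()})
    return report


# ---------------------------------------------------------------------------
# restraints

def _restraint_rows(report: StructureReport, refset: ReferenceSet, edits,
                    scale: float, rmsd_cutoff: float):
    """One row per (step, torsion): atoms, target (deg) and sigma (deg)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    edit_map = {e.step_name: e.target_ntc for e in (edits or [])}
    known = {rec.name for rec in report.steps}
    unknown = set(edit_map) - known
    if unknown:
        raise ValueError(f"edits reference unknown steps: {sorted(unknown)}")
    for target in edit_map.values():
        refset.get(target)  # raises on unknown class
    idx = {n: i for i, n in enumerate(PARAMETER_NAMES)}
    for rec in report.steps:
        a = rec.assignment
        edited = rec.name in edit_map
        if edited:
            target_ntc = edit_map[rec.name]
        elif a.assigned and a.rmsd_to_assigned is not None \
                and a.rmsd_to_assigned <= rmsd_cutoff:
            target_ntc = a.ntc
        else:
            continue
        cls = refset.get(target_ntc)
        for torsion in TORSION_NAMES:
            quad = TORSION_ATOMS[torsion]
            atoms = []
            for (ridx, role) in quad:
                ref = rec.step.first if ridx == 1 else rec.step.second
                atoms.append({"chain": ref.chain_id, "res_seq": ref.res_seq,
                              "ins_code": ref.ins_code,
                              "atom": rec.step.atoms[(ridx, role)].name})
            yield {
                "step_name": rec.name,
                "target_ntc": target_ntc,
                "edited": edited,
                "parameter": torsion,
                "atoms": atoms,
                "target": float(cls.means[idx[torsion]]),
                "sigma": float(cls.esd[idx[torsion]]) / scale,
            }


def write_restraints(report: StructureReport, refset: ReferenceSet, path,
                     edits=None, scale: float = 1.0,
                     rmsd_cutoff: float = DEFAULT_RESTRAINT_RMSD_CUTOFF,
                     dialect: str = "generic") -> Path:
    """Emit torsion restraints toward class-mean geometry.

    Each assigned step within ``rmsd_cutoff`` of its reference (or with an
    explicit edit, which also overrides the target class) contributes one
    restraint per prescribed torsion (the seven backbone torsions, the two
    glycosidic torsions and mu) with sigma = class e.s.d. / ``scale``.  The
    N-N and C1'-C1' distances are not restrained.  ``dialect`` is
    ``"generic"`` (CSV) or ``"refmac"`` (external torsion-restraint records).
    """
    rows = list(_restraint_rows(report, refset, edits, scale, rmsd_cutoff))
    path = Path(path)
    if dialect == "generic":
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        header = ["step_name", "target_ntc", "edited", "parameter"]
        for i in range(1, 5):
            header += [f"chain{i}", f"res_seq{i}", f"ins_code{i}", f"atom{i}"]
        header += ["target", "sigma"]
        w.writerow(header)
        for r in rows:
            row = [r["step_name"], r["target_ntc"], str(r["edited"]).lower(), r["parameter"]]
            for atom in r["atoms"]:
                row += [atom["chain"], atom["res_seq"], atom["ins_code"], atom["atom"]]
            row += [f"{r['target']:.2f}", f"{r['sigma']:.4f}"]
            w.writerow(row)
        path.write_text(buf.getvalue())
    elif dialect == "refmac":
        lines = ["# ntckit torsion restraints (refmac external-restraint dialect, v1)"]
        for r in rows:
            parts = ["exte", "tors"]
            for kw, atom in zip(("first", "next", "next", "next"), r["atoms"]):
                ins = atom["ins_code"] or "."
                parts += [kw, "chain", atom["chain"], "resi", str(atom["res_seq"]),
                          "ins", ins, "atom", atom["atom"]]
            parts += ["value", f"{r['target']:.2f}", "sigma", f"{r['sigma']:.4f}",
                      "period", "1"]
            lines.append(" ".join(parts))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown restraint dialect {dialect!r}")
    return path


def write_superposed_references(report: StructureReport, refset: ReferenceSet,
                                path) -> Path:
    """mmCIF with each assigned step's class representative superposed onto it.

    One model per assigned step, holding the representative's 18 atoms
    transformed by that step's optimal superposition.
    """
    structure = gemmi.Structure()
    structure.name = f"{report.source}_ntc_references"
    model_no = 0
    for rec in report.steps:
        a = rec.assignment
        if not a.assigned:
            continue
        rep = refset.get(a.ntc).representative
        if rep is None:
            continue
        moved = superpose_rmsd(rec.step.coords(), rep).transform(rep)
        model_no += 1
        model = gemmi.Model(model_no)
        chain = gemmi.Chain(rec.step.first.chain_id or "A")
        for ridx, ref in ((1, rec.step.first), (2, rec.step.second)):
            res = gemmi.Residue()
            res.name = ref.res_name
            res.seqid = gemmi.SeqId(ref.res_seq, ref.ins_code or " ")
            for (i_role, xyz) in zip(ATOM_ROLES, moved):
                if i_role[0] != ridx:
                    continue
                atom = gemmi.Atom()
                atom.name = rec.step.atoms[i_role].name
                atom.element = gemmi.Element(rec.step.atoms[i_role].element or "C")
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                atom.b_iso = 20.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    path = Path(path)
    doc = structure.make_mmcif_document()
    doc.write_file(str(path))
    return path
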