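"""ntckit: NtC/CANA structural-alphabet analysis of nucleic-acid structures.

Detects dinucleotide steps in mmCIF/PDB coordinate files, measures their 12
sugar-phosphate/glycosidic parameters, assigns each step to an NtC conformer
class (and its coarse CANA group) with a periodicity-aware weighted k-NN
classifier, scores the assignment with confal quality values, diagnoses
similarity and step-to-step connectivity, and emits refinement restraints.
"""

__version__ = "0.1.0"

from .classify import Assignment, DistanceProfile, NtCClassifier, assign_step, \
    parameter_distance
from .confal import confal_breakdown, parameter_confal, step_confal, \
    structure_confal, structure_percentile
from .diagnostics import connectivity, rmsd_band, similarity_profile, \
    suggest_alternatives
from .geometry import StepParameters, circular_difference, compute_step_parameters, \
    dihedral, superpose_rmsd
from .pipeline import PipelineConfig, RestraintEdit, StructureReport, read_report, \
    run_pipeline, write_report, write_restraints, write_superposed_references
from .reference import NtCClass, ReferenceSet, load_reference, save_reference
from .structure_io import DinucleotideStep, detect_steps, read_structure, step_name
from .synthetic import SyntheticSpec, build_dinucleotide, build_polymer, \
    generate_reference, sample_step_parameters

__all__ = [
    "Assignment", "DistanceProfile", "NtCClassifier", "assign_step",
    "parameter_distance", "confal_breakdown", "parameter_confal", "step_confal",
    "structure_confal", "structure_percentile", "connectivity", "rmsd_band",
    "similarity_profile", "suggest_alternatives", "StepParameters",
    "circular_difference", "compute_step_parameters", "dihedral", "superpose_rmsd",
    "PipelineConfig", "RestraintEdit", "StructureReport", "read_report",
    "run_pipeline", "write_report", "write_restraints",
    "write_superposed_references", "NtCClass", "ReferenceSet", "load_reference",
    "save_reference", "DinucleotideStep", "detect_steps", "read_structure",
    "step_name", "SyntheticSpec", "build_dinucleotide", "build_polymer",
    "generate_reference", "sample_step_parameters",
]
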