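"""The NtC conformer reference table: loading, validation, serving.

A reference set holds one :class:`NtCClass` per conformer class: the mean
and e.s.d. of the 12 step parameters, the allowed lower/upper displacement
borders used by the confal function, the CANA group symbol and the 18-atom
representative coordinates used for Cartesian r.m.s.d.  The published table
defines 96 classes grouped into 14 CANA symbols, plus the formally 97th
"unassigned" class for outliers; any table with the same schema (including
the synthetic ones) is accepted.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import PARAMETER_NAMES, signed_circular_difference, wrap_angle

__all__ = [
    "NtCClass",
    "ReferenceSet",
    "UNASSIGNED_NTC",
    "UNASSIGNED_CANA",
    "load_reference",
    "save_reference",
    "cana_of",
    "ReferenceValidationError",
]

UNASSIGNED_NTC = "NANT"
UNASSIGNED_CANA = "NAN"

#: default half-width of the allowed displacement borders, in e.s.d. units
DEFAULT_BORDER_FACTOR = 3.0

_N_CIRCULAR = 10


class ReferenceValidationError(ValueError):
    """Reference table fails a schema or consistency check."""


def _default_borders(means, esd, factor):
    half = factor * np.asarray(esd, dtype=float)
    if np.any(half[:_N_CIRCULAR] >= 180.0):
        raise ReferenceValidationError("border half-width >= 180 deg on a torsion")
    lower = np.asarray(means, dtype=float) - half
    upper = np.asarray(means, dtype=float) + half
    lower[:_N_CIRCULAR] = wrap_angle(lower[:_N_CIRCULAR])
    upper[:_N_CIRCULAR] = wrap_angle(upper[:_N_CIRCULAR])
    return lower, upper


@dataclass
class NtCClass:
    """One reference conformer class."""

    ntc: str
    cana: str
    means: np.ndarray
    esd: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    representative: np.ndarray | None = None  # (18, 3) in canonical role order
    frequency: float | None = None
    border_factor: float = DEFAULT_BORDER_FACTOR

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.esd = np.asarray(self.esd, dtype=float)
        if self.means.shape != (12,) or self.esd.shape != (12,):
            raise ReferenceValidationError(f"{self.ntc}: means/esd must have 12 entries")
        if np.any(~np.isfinite(self.means)) or np.any(~np.isfinite(self.esd)):
            raise ReferenceValidationError(f"{self.ntc}: non-finite means/esd")
        if np.any(self.esd <= 0):
            raise ReferenceValidationError(f"{self.ntc}: e.s.d. values must be positive")
        self.means[:_N_CIRCULAR] = wrap_angle(self.means[:_N_CIRCULAR])
        if self.lower is None or self.upper is None:
            self.lower, self.upper = _default_borders(self.means, self.esd, self.border_factor)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        lo = signed_circular_difference(self.lower[:_N_CIRCULAR], self.means[:_N_CIRCULAR])
        up = signed_circular_difference(self.upper[:_N_CIRCULAR], self.means[:_N_CIRCULAR])
        if np.any(lo >= 0) or np.any(up <= 0):
            raise ReferenceValidationError(
                f"{self.ntc}: borders must bracket the mean (circularly) on every torsion")
        if np.any(self.lower[_N_CIRCULAR:] >= self.means[_N_CIRCULAR:]) or \
           np.any(self.upper[_N_CIRCULAR:] <= self.means[_N_CIRCULAR:]):
            raise ReferenceValidationError(f"{self.ntc}: distance borders must bracket the mean")
        if self.representative is not None:
            self.representative = np.asarray(self.representative, dtype=float)
            if self.representative.shape != (18, 3):
                raise ReferenceValidationError(
                    f"{self.ntc}: representative must have 18 atoms (got "
                    f"{self.representative.shape})")


@dataclass
class ReferenceSet:
    classes: list = field(default_factory=list)
    version: str = ""
    unassigned_code: str = UNASSIGNED_NTC
    unassigned_cana: str = UNASSIGNED_CANA

    def __post_init__(self):
        codes = [c.ntc for c in self.classes]
        if len(set(codes)) != len(codes):
            raise ReferenceValidationError("duplicate NtC codes in reference set")
        self._by_code = {c.ntc: c for c in self.classes}

    def __len__(self):
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    @property
    def codes(self):
        return [c.ntc for c in self.classes]

    def get(self, ntc: str) -> NtCClass:
        try:
            return self._by_code[ntc]
        except KeyError:
            raise KeyError(f"unknown NtC code {ntc!r}") from None

    def cana_of(self, ntc: str) -> str:
        if ntc == self.unassigned_code:
            return self.unassigned_cana
        return self.get(ntc).cana

    def means_matrix(self) -> np.ndarray:
        return np.array([c.means for c in self.classes])

    def pooled_esd(self) -> np.ndarray:
        """Class-pooled e.s.d. per parameter (root mean square across classes)."""
        return np.sqrt(np.mean(np.array([c.esd for c in self.classes]) ** 2, axis=0))


def cana_of(refset: ReferenceSet, ntc: str) -> str:
    """CANA symbol of an NtC code; the unassigned code maps to the unassigned symbol."""
    return refset.cana_of(ntc)


# ---------------------------------------------------------------------------
# CSV / representative-archive serialization

_ALIASES = {
    "ntc": "ntc", "class": "ntc", "code": "ntc",
    "cana": "cana",
    "frequency": "frequency", "freq": "frequency", "occurrence": "frequency",
    "delta1": "delta1", "d1": "delta1", "delta": "delta1",
    "epsilon1": "epsilon1", "e1": "epsilon1", "eps1": "epsilon1", "epsilon": "epsilon1",
    "zeta1": "zeta1", "z1": "zeta1", "zeta": "zeta1",
    "alpha2": "alpha2", "a2": "alpha2", "alpha": "alpha2",
    "beta2": "beta2", "b2": "beta2", "beta": "beta2",
    "gamma2": "gamma2", "g2": "gamma2", "gamma": "gamma2",
    "delta2": "delta2", "d2": "delta2",
    "chi1": "chi1", "ch1": "chi1",
    "chi2": "chi2", "ch2": "chi2",
    "mu": "mu",
    "dist_nn": "dist_NN", "nn": "dist_NN", "nn1n9": "dist_NN",
    "dist_cc": "dist_CC", "cc": "dist_CC", "c1c1": "dist_CC",
}


def _normalize_columns(df: pd.DataFrame, path) -> pd.DataFrame:
    renamed = {}
    for col in df.columns:
        key = str(col).strip().lower().replace("'", "").replace("-", "_").replace(" ", "_")
        if key in _ALIASES:
            renamed[col] = _ALIASES[key]
        elif key.startswith(("lower_", "upper_")):
            side, _, rest = key.partition("_")
            if rest in _ALIASES:
                renamed[col] = f"{side}_{_ALIASES[rest]}"
    df = df.rename(columns=renamed)
    if "ntc" not in df.columns:
        raise ReferenceValidationError(f"{path}: no NtC code column found")
    missing = [p for p in PARAMETER_NAMES if p not in df.columns]
    if missing:
        raise ReferenceValidationError(f"{path}: missing parameter columns {missing}")
    return df


def _read_representative(text: str, source: str) -> np.ndarray:
    """Extract the 18 canonical atoms, in role order, from a 2-residue PDB file."""
    import gemmi

    from .structure_io import ATOM_ROLES, _atom_map, _base_atoms

    structure = gemmi.read_pdb_string(text)
    residues = [r for model in structure for ch in model for r in ch if not r.is_water()]
    if len(residues) < 2:
        raise ReferenceValidationError(f"{source}: representative needs 2 residues")
    coords = []
    for idx, res in ((1, residues[0]), (2, residues[1])):
        amap = _atom_map(res)
        base = _base_atoms(amap)
        if base is None:
            raise ReferenceValidationError(f"{source}: no base attachment atoms")
        names = {"N": base[0], "C": base[1]}
        for ridx, role in ATOM_ROLES:
            if ridx != idx:
                continue
            name = names.get(role, role)
            variants = amap.get(name)
            if not variants:
                raise ReferenceValidationError(f"{source}: missing atom {name} in residue {idx}")
            atom = variants.get("", next(iter(variants.values())))
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return np.array(coords)


def _load_representatives(source) -> dict:
    source = Path(source)
    reps = {}
    if source.is_dir():
        for f in sorted(source.glob("*.pdb")):
            reps[f.stem] = _read_representative(f.read_text(), str(f))
    elif zipfile.is_zipfile(source):
        with zipfile.ZipFile(source) as zf:
            for info in sorted(zf.infolist(), key=lambda i: i.filename):
                if info.filename.lower().endswith(".pdb"):
                    stem = Path(info.filename).stem
                    reps[stem] = _read_representative(
                        zf.read(info).decode(), f"{source}:{info.filename}")
    else:
        raise ReferenceValidationError(
            f"{source}: representatives must be a directory or ZIP of PDB files")
    return reps


def load_reference(means_csv, esd_csv, representatives=None,
                   border_factor: float = DEFAULT_BORDER_FACTOR,
                   version: str = "") -> ReferenceSet:
    """Load a conformer table from its CSV pair and representative archive.

    ``means_csv`` carries one row per class with the NtC code, the CANA
    symbol and the 12 parameter means (optionally explicit
    ``lower_``/``upper_`` border columns and a frequency); ``esd_csv``
    carries the matching e.s.d. values.  ``representatives`` is a directory
    or ZIP of PDB files named ``<NTC>.pdb``.  When borders are not explicit
    they default to mean +/- ``border_factor`` x e.s.d.
    """
    means_df = _normalize_columns(pd.read_csv(means_csv), means_csv)
    esd_df = _normalize_columns(pd.read_csv(esd_csv), esd_csv)
    esd_by_code = {str(r["ntc"]): r for _, r in esd_df.iterrows()}
    reps = _load_representatives(representatives) if representatives is not None else {}

    classes = []
    for _, row in means_df.iterrows():
        code = str(row["ntc"])
        if code not in esd_by_code:
            raise ReferenceValidationError(f"class {code} missing from e.s.d. table")
        esd_row = esd_by_code[code]
        means = np.array([float(row[p]) for p in PARAMETER_NAMES])
        esd = np.array([float(esd_row[p]) for p in PARAMETER_NAMES])
        lower = upper = None
        if all(f"lower_{p}" in means_df.columns for p in PARAMETER_NAMES):
            lower = np.array([float(row[f"lower_{p}"]) for p in PARAMETER_NAMES])
            upper = np.array([float(row[f"upper_{p}"]) for p in PARAMETER_NAMES])
        rep = reps.get(code)
        if representatives is not None and rep is None:
            raise ReferenceValidationError(f"class {code} has no representative file")
        classes.append(NtCClass(
            ntc=code,
            cana=str(row["cana"]) if "cana" in means_df.columns else "",
            means=means, esd=esd, lower=lower, upper=upper,
            representative=rep,
            frequency=float(row["frequency"]) if "frequency" in means_df.columns
            and pd.notna(row["frequency"]) else None,
            border_factor=border_factor,
        ))
    return ReferenceSet(classes=classes, version=version)


def save_reference(refset: ReferenceSet, directory) -> dict:
    """Write a reference set as means.csv + esd.csv + representatives/ PDB files.

    Returns the paths written.  ``load_reference`` on the result reproduces
    the set (load -> save -> load is idempotent).
    """
    from .structure_io import ATOM_ROLES

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    means_rows, esd_rows = [], []
    for cls in refset:
        row = {"ntc": cls.ntc, "cana": cls.cana}
        row.update({p: cls.means[i] for i, p in enumerate(PARAMETER_NAMES)})
        row.update({f"lower_{p}": cls.lower[i] for i, p in enumerate(PARAMETER_NAMES)})
        row.update({f"upper_{p}": cls.upper[i] for i, p in enumerate(PARAMETER_NAMES)})
        if cls.frequency is not None:
            row["frequency"] = cls.frequency
        means_rows.append(row)
        erow = {"ntc": cls.ntc}
        erow.update({p: cls.esd[i] for i, p in enumerate(PARAMETER_NAMES)})
        esd_rows.append(erow)
    means_path = directory / "means.csv"
    esd_path = directory / "esd.csv"
    pd.DataFrame(means_rows).to_csv(means_path, index=False, float_format="%.6f")
    pd.DataFrame(esd_rows).to_csv(esd_path, index=False, float_format="%.6f")

    reps_dir = directory / "representatives"
    reps_dir.mkdir(exist_ok=True)
    for cls in refset:
        if cls.representative is None:
            continue
        lines = []
        serial = 0
        for (ridx, role), xyz in zip(ATOM_ROLES, cls.representative):
            serial += 1
            name = {"N": "N9", "C": "C4"}.get(role, role)
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} DA A{ridx:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{20.0:6.2f}"
                f"          {element:>2s}")
        lines.append("END")
        (reps_dir / f"{cls.ntc}.pdb").write_text("\n".join(lines) + "\n")
    return {"means": means_path, "esd": esd_path, "representatives": reps_dir}
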