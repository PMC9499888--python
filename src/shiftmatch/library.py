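"""Shift-library data model and readers/writers.

A reference library is a collection of molecules, each carrying the full,
per-nucleus lists of its 13C and 1H chemical shifts in ppm. Every nucleus is
listed individually — chemically equivalent nuclei (e.g. the three protons of
a methyl group) each get their own entry — because the assignment matrix used
for scoring is defined over all nuclei, and per-molecule nucleus totals only
add up under per-atom listing.

Two canonical on-disk formats are supported:

* long CSV — one row per nucleus, columns ``molecule_id, solvent, smiles,
  nucleus, shift_ppm`` with ``nucleus`` one of ``13C``/``1H``;
* JSON — one object per molecule with two shift arrays.

Both round-trip exactly: shifts are serialized with ``repr`` so the decimal
text recovers the identical float. A third format, ``mol-dir``, ingests a
directory shaped like a supplementary-data drop: a tab-separated shift table
(``shifts.tsv``) plus optional per-molecule MOL files (used only to recover a
SMILES string when RDKit is available).
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ShiftRecord",
    "ShiftLibrary",
    "LibrarySummary",
    "LibraryError",
    "read_library",
    "write_library",
    "summarize",
]

#: Nucleus labels used throughout (and in the canonical CSV).
CARBON = "13C"
PROTON = "1H"


class LibraryError(ValueError):
    """Raised for malformed library files or invariant violations."""


def _as_shift_tuple(values: Iterable[float], *, what: str, molecule_id: str) -> tuple[float, ...]:
    out = []
    for v in values:
        x = float(v)
        if not math.isfinite(x):
            raise LibraryError(f"non-finite {what} shift {v!r} for molecule {molecule_id!r}")
        out.append(x)
    return tuple(out)


@dataclass(frozen=True)
class ShiftRecord:
    """One molecule: identity plus its per-nucleus 13C and 1H shift lists (ppm).

    At least one of the two lists must be non-empty; list lengths equal the
    molecule's nucleus counts (no symmetry collapsing).
    """

    molecule_id: str
    carbon_shifts: tuple[float, ...] = ()
    proton_shifts: tuple[float, ...] = ()
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.molecule_id:
            raise LibraryError("molecule_id must be a non-empty string")
        object.__setattr__(
            self,
            "carbon_shifts",
            _as_shift_tuple(self.carbon_shifts, what="carbon", molecule_id=self.molecule_id),
        )
        object.__setattr__(
            self,
            "proton_shifts",
            _as_shift_tuple(self.proton_shifts, what="proton", molecule_id=self.molecule_id),
        )
        if not self.carbon_shifts and not self.proton_shifts:
            raise LibraryError(
                f"molecule {self.molecule_id!r} has neither carbon nor proton shifts"
            )

    @property
    def n_carbon(self) -> int:
        return len(self.carbon_shifts)

    @property
    def n_hydrogen(self) -> int:
        return len(self.proton_shifts)

    def shifts(self, nucleus: str) -> tuple[float, ...]:
        if nucleus == CARBON:
            return self.carbon_shifts
        if nucleus == PROTON:
            return self.proton_shifts
        raise ValueError(f"unknown nucleus {nucleus!r}")


class ShiftLibrary:
    """An ordered collection of :class:`ShiftRecord` with a (nC, nH) count index.

    The count index maps each (carbon count, hydrogen count) pair to the set
    of molecule ids with exactly those counts; it is the backbone of candidate
    filtering for both pure samples and mixtures.
    """

    def __init__(self, records: Sequence[ShiftRecord], solvent: str = "unspecified"):
        if not records:
            raise LibraryError("a shift library must contain at least one molecule")
        by_id: dict[str, ShiftRecord] = {}
        for rec in records:
            if rec.molecule_id in by_id:
                raise LibraryError(f"duplicate molecule_id {rec.molecule_id!r}")
            by_id[rec.molecule_id] = rec
        self._records: tuple[ShiftRecord, ...] = tuple(records)
        self._by_id = by_id
        self.solvent = solvent
        index: dict[tuple[int, int], set[str]] = {}
        for rec in self._records:
            index.setdefault((rec.n_carbon, rec.n_hydrogen), set()).add(rec.molecule_id)
        self._count_index = index

    @property
    def records(self) -> tuple[ShiftRecord, ...]:
        return self._records

    @property
    def count_index(self) -> Mapping[tuple[int, int], set[str]]:
        return self._count_index

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ShiftRecord]:
        return iter(self._records)

    def __contains__(self, molecule_id: str) -> bool:
        return molecule_id in self._by_id

    def __getitem__(self, molecule_id: str) -> ShiftRecord:
        try:
            return self._by_id[molecule_id]
        except KeyError:
            raise KeyError(f"no molecule {molecule_id!r} in library") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShiftLibrary):
            return NotImplemented
        return self.solvent == other.solvent and self._records == other._records

    def __repr__(self) -> str:
        return f"ShiftLibrary({len(self)} molecules, solvent={self.solvent!r})"


@dataclass(frozen=True)
class LibrarySummary:
    """Totals and per-molecule count histograms for a library."""

    n_molecules: int
    n_carbon_nuclei: int
    n_hydrogen_nuclei: int
    carbon_count_histogram: Mapping[int, int] = field(default_factory=dict)
    hydrogen_count_histogram: Mapping[int, int] = field(default_factory=dict)


def summarize(lib: ShiftLibrary) -> LibrarySummary:
    """Count molecules and nuclei, and histogram per-molecule nucleus counts."""
    c_hist: dict[int, int] = {}
    h_hist: dict[int, int] = {}
    n_c = 0
    n_h = 0
    for rec in lib:
        n_c += rec.n_carbon
        n_h += rec.n_hydrogen
        c_hist[rec.n_carbon] = c_hist.get(rec.n_carbon, 0) + 1
        h_hist[rec.n_hydrogen] = h_hist.get(rec.n_hydrogen, 0) + 1
    return LibrarySummary(
        n_molecules=len(lib),
        n_carbon_nuclei=n_c,
        n_hydrogen_nuclei=n_h,
        carbon_count_histogram=dict(sorted(c_hist.items())),
        hydrogen_count_histogram=dict(sorted(h_hist.items())),
    )


# ---------------------------------------------------------------------------
# readers / writers

_CSV_COLUMNS = ["molecule_id", "solvent", "smiles", "nucleus", "shift_ppm"]


def _apply_affine(shift: float, affine: tuple[float, float] | None) -> float:
    # optional referencing correction for raw prediction output: shift -> m*shift + b
    if affine is None:
        return shift
    m, b = affine
    return m * shift + b


def _read_csv(path: str, affine: tuple[float, float] | None) -> ShiftLibrary:
    order: list[str] = []
    carbons: dict[str, list[float]] = {}
    protons: dict[str, list[float]] = {}
    smiles: dict[str, str | None] = {}
    solvent = "unspecified"
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "molecule_id" not in reader.fieldnames:
            raise LibraryError(f"{path}: missing header row with molecule_id column")
        for lineno, row in enumerate(reader, start=2):
            mid = row["molecule_id"]
            if mid not in carbons:
                order.append(mid)
                carbons[mid] = []
                protons[mid] = []
                smiles[mid] = row.get("smiles") or None
            if row.get("solvent"):
                solvent = row["solvent"]
            nucleus = row["nucleus"]
            try:
                value = float(row["shift_ppm"])
            except (TypeError, ValueError):
                raise LibraryError(
                    f"{path} line {lineno}: non-numeric shift {row.get('shift_ppm')!r}"
                ) from None
            if not math.isfinite(value):
                raise LibraryError(f"{path} line {lineno}: non-finite shift {value!r}")
            value = _apply_affine(value, affine)
            if nucleus == CARBON:
                carbons[mid].append(value)
            elif nucleus == PROTON:
                protons[mid].append(value)
            else:
                raise LibraryError(f"{path} line {lineno}: unknown nucleus {nucleus!r}")
    if not order:
        raise LibraryError(f"{path}: empty library")
    records = [
        ShiftRecord(mid, tuple(carbons[mid]), tuple(protons[mid]), smiles[mid]) for mid in order
    ]
    return ShiftLibrary(records, solvent=solvent)


def _read_json(path: str, affine: tuple[float, float] | None) -> ShiftLibrary:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    molecules = payload.get("molecules")
    if not molecules:
        raise LibraryError(f"{path}: empty library")
    records = []
    for entry in molecules:
        records.append(
            ShiftRecord(
                molecule_id=entry["molecule_id"],
                carbon_shifts=tuple(
                    _apply_affine(float(v), affine) for v in entry.get("carbon_shifts", [])
                ),
                proton_shifts=tuple(
                    _apply_affine(float(v), affine) for v in entry.get("proton_shifts", [])
                ),
                smiles=entry.get("smiles"),
            )
        )
    return ShiftLibrary(records, solvent=payload.get("solvent", "unspecified"))


def _smiles_from_mol(mol_path: str) -> str | None:
    try:
        from rdkit import Chem  # optional dependency
    except ImportError:
        return None
    mol = Chem.MolFromMolFile(mol_path, sanitize=False)
    if mol is None:
        return None
    try:
        return Chem.MolToSmiles(mol)
    except Exception:
        return None


def _read_mol_dir(
    path: str, affine: tuple[float, float] | None, solvent: str = "unspecified"
) -> ShiftLibrary:
    """Directory with a tab-separated shift table plus optional MOL files.

    ``shifts.tsv`` columns: molecule_id, nucleus (13C|1H), shift_ppm. MOL
    files named ``<molecule_id>.mol`` contribute a SMILES string when RDKit
    can parse them; they are otherwise pass-through.
    """
    table = os.path.join(path, "shifts.tsv")
    if not os.path.exists(table):
        raise LibraryError(f"{path}: missing shift table shifts.tsv")
    order: list[str] = []
    carbons: dict[str, list[float]] = {}
    protons: dict[str, list[float]] = {}
    with open(table, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "molecule_id":
                continue
            if len(parts) != 3:
                raise LibraryError(f"{table} line {lineno}: expected 3 tab-separated fields")
            mid, nucleus, raw = parts
            if mid not in carbons:
                order.append(mid)
                carbons[mid] = []
                protons[mid] = []
            try:
                value = float(raw)
            except ValueError:
                raise LibraryError(f"{table} line {lineno}: non-numeric shift {raw!r}") from None
            if not math.isfinite(value):
                raise LibraryError(f"{table} line {lineno}: non-finite shift {raw!r}")
            value = _apply_affine(value, affine)
            if nucleus == CARBON:
                carbons[mid].append(value)
            elif nucleus == PROTON:
                protons[mid].append(value)
            else:
                raise LibraryError(f"{table} line {lineno}: unknown nucleus {nucleus!r}")
    if not order:
        raise LibraryError(f"{table}: empty library")
    records = []
    for mid in order:
        mol_path = os.path.join(path, f"{mid}.mol")
        smi = _smiles_from_mol(mol_path) if os.path.exists(mol_path) else None
        records.append(ShiftRecord(mid, tuple(carbons[mid]), tuple(protons[mid]), smi))
    return ShiftLibrary(records, solvent=solvent)


def read_library(
    path: str,
    format: str = "csv",
    affine: tuple[float, float] | None = None,
    solvent: str | None = None,
) -> ShiftLibrary:
    """Read a shift library.

    Parameters
    ----------
    path:
        File (csv/json) or directory (mol-dir) location.
    format:
        ``"csv"``, ``"json"`` or ``"mol-dir"``.
    affine:
        Optional referencing correction ``(slope, intercept)`` applied to
        every shift at read time as ``slope * shift + intercept``; use when
        the on-disk values are unreferenced prediction output.
    solvent:
        Override the solvent label (mol-dir has nowhere to store one).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "csv":
        lib = _read_csv(path, affine)
    elif format == "json":
        lib = _read_json(path, affine)
    elif format == "mol-dir":
        lib = _read_mol_dir(path, affine, solvent=solvent or "unspecified")
    else:
        raise ValueError(f"unknown library format {format!r}")
    if solvent is not None:
        lib.solvent = solvent
    return lib


def write_library(lib: ShiftLibrary, path: str, format: str = "csv") -> str:
    """Write a library so that :func:`read_library` reproduces it exactly."""
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for rec in lib:
                smi = rec.smiles or ""
                for nucleus, shifts in ((CARBON, rec.carbon_shifts), (PROTON, rec.proton_shifts)):
                    for value in shifts:
                        writer.writerow([rec.molecule_id, lib.solvent, smi, nucleus, repr(value)])
    elif format == "json":
        payload = {
            "format": "shift-library",
            "solvent": lib.solvent,
            "molecules": [
                {
                    "molecule_id": rec.molecule_id,
                    "smiles": rec.smiles,
                    "carbon_shifts": list(rec.carbon_shifts),
                    "proton_shifts": list(rec.proton_shifts),
                }
                for rec in lib
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown library format {format!r}")
    return path
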