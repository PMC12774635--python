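"""Readers and writers for every external artifact the pipeline touches.

Structural models (mmCIF/PDB via gemmi), AlphaFold-style confidence
summaries and PAE matrices (JSON), FoldX ``BuildModel``/``AnalyseComplex``
output files (``.fxout`` text dialects), FoldX ``individual_list`` mutation
lines, and SNP-SELEX-style PBS tables (TSV).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "ConfidenceSummary",
    "PaeMatrix",
    "EnergyRecord",
    "AllelePair",
    "MutationSpec",
    "ModelIOError",
    "FormatError",
    "ChainClassificationError",
    "read_structure_model",
    "write_structure_pdb",
    "write_structure_mmcif",
    "read_confidence_summary",
    "read_pae_matrix",
    "parse_foldx_buildmodel",
    "parse_foldx_analysecomplex",
    "write_individual_list",
    "read_pbs_table",
    "write_pbs_table",
]

#: Residue vocabularies used to classify chains.
PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
DNA_RESIDUES = {"DA", "DC", "DG", "DT"}

VALID_BASES = {"A", "C", "G", "T"}


class ModelIOError(Exception):
    """Base class for I/O errors raised by this module."""


class FormatError(ModelIOError):
    """A file could not be parsed in the declared format."""


class ChainClassificationError(ModelIOError):
    """A chain mixes protein and DNA residue vocabularies."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_pos: int  # 1-based
    residue_name: str


@dataclass(frozen=True)
class Atom:
    chain_id: str
    seq_pos: int
    atom_name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class StructureModel:
    """One TF-DNA complex model: chains, residues and atoms in angstroms."""

    model_id: str
    chains: list[tuple[str, str]]  # (chain_id, polymer_kind: "protein"|"dna")
    residues: list[Residue]
    atoms: list[Atom]

    def __post_init__(self) -> None:
        keys = [(r.chain_id, r.seq_pos) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain_id, seq_pos) residue keys")
        keyset = set(keys)
        for a in self.atoms:
            if (a.chain_id, a.seq_pos) not in keyset:
                raise ValueError(
                    f"atom {a.atom_name} references missing residue "
                    f"({a.chain_id}, {a.seq_pos})"
                )
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinate on atom {a.atom_name}")

    @property
    def chain_kinds(self) -> dict[str, str]:
        return dict(self.chains)

    def chain_residues(self, chain_id: str) -> list[Residue]:
        """Residues of one chain in ascending sequence position."""
        res = [r for r in self.residues if r.chain_id == chain_id]
        return sorted(res, key=lambda r: r.seq_pos)

    def dna_chain_ids(self) -> list[str]:
        return [cid for cid, kind in self.chains if kind == "dna"]

    def protein_chain_ids(self) -> list[str]:
        return [cid for cid, kind in self.chains if kind == "protein"]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array in the atom list's order."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class ConfidenceSummary:
    """Interface confidence extracted from a model's summary JSON."""

    model_id: str
    iptm: float
    ptm: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.iptm <= 1.0):
            raise ValueError(f"iptm {self.iptm} outside [0, 1]")


@dataclass(frozen=True)
class PaeMatrix:
    """Predicted-aligned-error matrix aligned to concatenated residue order."""

    model_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"PAE matrix not square: shape {v.shape}")
        if (v < 0).any():
            raise ValueError("PAE entries must be >= 0")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EnergyRecord:
    """FoldX-derived energies for one allele pair (kcal/mol).

    ``ddg_fwd`` scores the ref->alt mutation built on the reference model;
    ``ddg_rev`` the alt->ref mutation on the alternative model.  Partial
    records keep ``None`` in the missing slots — they are never zero-filled.
    """

    pair_id: str
    ddg_fwd: float | None = None
    ddg_rev: float | None = None
    interface_ref: float | None = None
    interface_alt: float | None = None

    def __post_init__(self) -> None:
        for name in ("ddg_fwd", "ddg_rev", "interface_ref", "interface_alt"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{name} is not finite: {v}")

    @property
    def complete(self) -> bool:
        return None not in (
            self.ddg_fwd, self.ddg_rev, self.interface_ref, self.interface_alt
        )


@dataclass(frozen=True)
class AllelePair:
    """One SNP-SELEX-style record: a TF, a ref/alt oligo pair and its PBS."""

    pair_id: str
    tf: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_oligo: str
    alt_oligo: str
    variant_offset: int  # 1-based within the oligo
    pbs: float
    pbs_p: float

    def __post_init__(self) -> None:
        if len(self.ref_oligo) != len(self.alt_oligo):
            raise ValueError("oligos differ in length")
        mismatches = [
            i + 1
            for i, (a, b) in enumerate(zip(self.ref_oligo, self.alt_oligo))
            if a != b
        ]
        if mismatches != [self.variant_offset]:
            raise ValueError(
                f"oligos must differ only at offset {self.variant_offset}; "
                f"mismatches at {mismatches}"
            )
        if self.ref_oligo[self.variant_offset - 1] != self.ref_allele:
            raise ValueError("ref_oligo does not carry ref_allele at offset")
        if self.alt_oligo[self.variant_offset - 1] != self.alt_allele:
            raise ValueError("alt_oligo does not carry alt_allele at offset")
        if not (0.0 <= self.pbs_p <= 1.0):
            raise ValueError(f"pbs_p {self.pbs_p} outside [0, 1]")


@dataclass(frozen=True)
class MutationSpec:
    """A single DNA point mutation in FoldX ``individual_list`` terms."""

    chain_id: str
    seq_pos: int
    from_base: str
    to_base: str

    def __post_init__(self) -> None:
        if self.from_base not in VALID_BASES or self.to_base not in VALID_BASES:
            raise ValueError("bases must be one of A, C, G, T")
        if self.from_base == self.to_base:
            raise ValueError("identity mutation (from_base == to_base)")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _classify_chain(chain_id: str, residue_names: Iterable[str]) -> str:
    names = set(residue_names)
    if names <= PROTEIN_RESIDUES:
        return "protein"
    if names <= DNA_RESIDUES:
        return "dna"
    unknown = names - PROTEIN_RESIDUES - DNA_RESIDUES
    raise ChainClassificationError(
        f"chain {chain_id!r} mixes residue vocabularies "
        f"(protein={sorted(names & PROTEIN_RESIDUES)}, "
        f"dna={sorted(names & DNA_RESIDUES)}, other={sorted(unknown)})"
    )


def read_structure_model(path: str | Path, format: str = "auto") -> StructureModel:
    """Read one TF-DNA complex model from mmCIF or PDB.

    Chains are classified as protein or DNA from their residue vocabulary
    (standard amino acids vs DA/DC/DG/DT); a chain mixing the two raises
    :class:`ChainClassificationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise FormatError(f"{path}: no atoms found")

    chains: list[tuple[str, str]] = []
    residues: list[Residue] = []
    atoms: list[Atom] = []
    model = st[0]
    for ch in model:
        resnames = []
        for res in ch:
            resnames.append(res.name)
            residues.append(Residue(ch.name, res.seqid.num, res.name))
            for at in res:
                atoms.append(
                    Atom(
                        ch.name,
                        res.seqid.num,
                        at.name,
                        at.element.name,
                        at.pos.x,
                        at.pos.y,
                        at.pos.z,
                    )
                )
        chains.append((ch.name, _classify_chain(ch.name, resnames)))
    return StructureModel(
        model_id=path.stem, chains=chains, residues=residues, atoms=atoms
    )


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    atom_index: dict[tuple[str, int], list[Atom]] = {}
    for a in model.atoms:
        atom_index.setdefault((a.chain_id, a.seq_pos), []).append(a)
    for chain_id, _kind in model.chains:
        gc = gemmi.Chain(chain_id)
        for res in model.chain_residues(chain_id):
            gr = gemmi.Residue()
            gr.name = res.residue_name
            gr.seqid = gemmi.SeqId(res.seq_pos, " ")
            for a in atom_index.get((res.chain_id, res.seq_pos), []):
                ga = gemmi.Atom()
                ga.name = a.atom_name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(a.x, a.y, a.z)
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure_pdb(model: StructureModel, path: str | Path) -> None:
    """Serialize to PDB (coordinates kept to the format's 3 decimals)."""
    _to_gemmi(model).write_pdb(str(path))


def write_structure_mmcif(model: StructureModel, path: str | Path) -> None:
    _to_gemmi(model).make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# Confidence summaries and PAE
# ---------------------------------------------------------------------------

_IPTM_KEYS = ("iptm", "ipTM")
_PTM_KEYS = ("ptm", "pTM")


def _find_numeric(obj: Mapping, keys: Sequence[str]) -> list[float]:
    """All values found under any of ``keys``, searching one nesting level
    of ``summary_confidences`` as well (local-AF3 layout)."""
    found = []
    for k in keys:
        if k in obj:
            found.append(obj[k])
    nested = obj.get("summary_confidences")
    if isinstance(nested, Mapping):
        for k in keys:
            if k in nested:
                found.append(nested[k])
    return found


def read_confidence_summary(path: str | Path, model_id: str | None = None) -> ConfidenceSummary:
    """Read an ipTM (and optional pTM) from a model-confidence JSON.

    Accepts both ``iptm`` and ``ipTM`` spellings, at top level or nested
    under ``summary_confidences``.  A missing or non-numeric ipTM is an
    error — there is no default.  Two conflicting spellings are an error.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(obj, Mapping):
        raise FormatError(f"{path}: confidence JSON must be an object")
    iptms = _find_numeric(obj, _IPTM_KEYS)
    if not iptms:
        raise FormatError(f"{path}: no ipTM field (looked for {_IPTM_KEYS})")
    vals = set()
    for v in iptms:
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise FormatError(f"{path}: non-numeric ipTM value {v!r}")
        vals.add(float(v))
    if len(vals) > 1:
        raise FormatError(f"{path}: conflicting ipTM values {sorted(vals)}")
    iptm = vals.pop()
    ptms = _find_numeric(obj, _PTM_KEYS)
    ptm = float(ptms[0]) if ptms else None
    return ConfidenceSummary(model_id=model_id or path.stem, iptm=iptm, ptm=ptm)


def read_pae_matrix(path: str | Path, n_expected: int, model_id: str | None = None) -> PaeMatrix:
    """Read a JSON-encoded square PAE matrix and check its dimension.

    Accepts a bare 2-D array, or an object holding one under ``pae`` /
    ``predicted_aligned_error``.
    """
    path = Path(path)
    with open(path) as fh:
        obj = json.load(fh)
    if isinstance(obj, Mapping):
        for key in ("pae", "predicted_aligned_error"):
            if key in obj:
                obj = obj[key]
                break
        else:
            raise FormatError(f"{path}: no PAE array found")
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise FormatError(f"{path}: PAE matrix not square (shape {arr.shape})")
    if arr.shape[0] != n_expected:
        raise FormatError(
            f"{path}: PAE dimension {arr.shape[0]} != expected {n_expected}"
        )
    return PaeMatrix(model_id=model_id or path.stem, values=arr)


# ---------------------------------------------------------------------------
# FoldX output dialects
# ---------------------------------------------------------------------------

def _fxout_rows(path: Path) -> list[list[str]]:
    """Data rows of an fxout file: every line whose first field ends in
    ``.pdb``, split on tabs or runs of spaces.  Header drift across FoldX
    versions is absorbed by the .pdb rule."""
    rows = []
    for line in path.read_text().splitlines():
        fields = re.split(r"\t|\s{2,}| ", line.strip())
        fields = [f for f in fields if f]
        if fields and fields[0].lower().endswith(".pdb"):
            rows.append(fields)
    return rows


def parse_foldx_buildmodel(path: str | Path) -> tuple[str, float]:
    """Parse a FoldX ``Dif_*.fxout`` file into (pair_id, total ddG).

    The second column of each data row is the total energy difference of
    one run; multiple runs are averaged.
    """
    path = Path(path)
    rows = _fxout_rows(path)
    if not rows:
        raise FormatError(f"{path}: no data rows (no line starting with *.pdb)")
    energies = []
    for row in rows:
        if len(row) < 2:
            raise FormatError(f"{path}: data row has no energy column: {row}")
        try:
            energies.append(float(row[1]))
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric energy {row[1]!r}"
            ) from exc
    pair_id = re.sub(r"(_\d+)?\.pdb$", "", rows[0][0], flags=re.IGNORECASE)
    return pair_id, float(np.mean(energies))


def parse_foldx_analysecomplex(
    path: str | Path,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> float:
    """Sum the interface interaction energy between two chain groups.

    Parses the ``Interaction_*.fxout`` dialect: data rows carry the model
    file, the two chain identifiers and an interaction energy (located via
    an "Interaction Energy" header column when present, else the FoldX
    default position).  Every (a, b) chain pair across the two groups must
    appear; a missing pair raises an error listing the pairs found.
    """
    path = Path(path)
    group_a, group_b = set(group_a), set(group_b)
    text = path.read_text().splitlines()
    energy_col = 5  # FoldX default: Pdb, Group1, Group2, clashes1, clashes2, IE
    for line in text:
        if "Interaction Energy" in line:
            cols = [c.strip() for c in re.split(r"\t|\s{2,}", line) if c.strip()]
            for i, c in enumerate(cols):
                if c == "Interaction Energy":
                    energy_col = i
    rows = _fxout_rows(path)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    pair_energy: dict[frozenset[str], float] = {}
    for row in rows:
        if len(row) <= energy_col:
            raise FormatError(f"{path}: row too short for energy column: {row}")
        c1, c2 = row[1], row[2]
        try:
            e = float(row[energy_col])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric energy {row[energy_col]!r}") from exc
        pair_energy[frozenset((c1, c2))] = e
    wanted = [frozenset((a, b)) for a in group_a for b in group_b if a != b]
    missing = [p for p in wanted if p not in pair_energy]
    if missing:
        avail = sorted(tuple(sorted(p)) for p in pair_energy)
        miss = sorted(tuple(sorted(p)) for p in missing)
        raise FormatError(
            f"{path}: chain pairs {miss} not found; available pairs: {avail}"
        )
    return float(sum(pair_energy[p] for p in wanted))


def write_individual_list(spec: MutationSpec) -> str:
    """Emit one FoldX ``individual_list`` DNA-mutation line.

    Format: lowercase source base, chain, position, lowercase target base,
    terminating semicolon — e.g. chain B position 21 T->C gives ``tB21c;``.
    FoldX itself mutates the paired base on the complementary strand.
    """
    return (
        f"{spec.from_base.lower()}{spec.chain_id}{spec.seq_pos}"
        f"{spec.to_base.lower()};"
    )


# ---------------------------------------------------------------------------
# PBS tables
# ---------------------------------------------------------------------------

PBS_COLUMNS = (
    "pair_id", "tf", "chrom", "pos", "ref", "alt",
    "ref_oligo", "alt_oligo", "variant_offset", "pbs", "pbs_p",
)


def read_pbs_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[AllelePair]:
    """Read a SNP-SELEX-style PBS table (TSV with header).

    ``column_map`` renames nonstandard headers to the expected schema,
    e.g. ``{"p_value": "pbs_p"}``.  Rows violating the allele-pair
    invariants are rejected collectively with their 1-based row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in PBS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    pairs: list[AllelePair] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pairs.append(
                AllelePair(
                    pair_id=str(row.pair_id),
                    tf=str(row.tf),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref_allele=str(row.ref),
                    alt_allele=str(row.alt),
                    ref_oligo=str(row.ref_oligo),
                    alt_oligo=str(row.alt_oligo),
                    variant_offset=int(row.variant_offset),
                    pbs=float(row.pbs),
                    pbs_p=float(row.pbs_p),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((i, str(exc)))
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad)
        raise FormatError(f"{path}: {len(bad)} invalid row(s): {detail}")
    return pairs


def write_pbs_table(pairs: Sequence[AllelePair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "tf": [p.tf for p in pairs],
            "chrom": [p.chrom for p in pairs],
            "pos": [p.pos for p in pairs],
            "ref": [p.ref_allele for p in pairs],
            "alt": [p.alt_allele for p in pairs],
            "ref_oligo": [p.ref_oligo for p in pairs],
            "alt_oligo": [p.alt_oligo for p in pairs],
            "variant_offset": [p.variant_offset for p in pairs],
            "pbs": [p.pbs for p in pairs],
            "pbs_p": [p.pbs_p for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)
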