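"""Atomic model I/O, residue classification and score-atom selection.

Models are read from PDB or mmCIF through gemmi into plain records.  Residue
categories decide which atoms enter the backbone fit score: protein residues
contribute N, Cα and C (the carbonyl oxygen is excluded — its density is
typically weak at resolutions worse than ~3 Å), nucleotides contribute the
sugar-phosphate backbone (C1'–C5', O3', O4', O5', P), and ligands and waters
contribute all non-hydrogen atoms.  A Cα-only mode (C1' for nucleic acids)
supports backbone-only models built into low-resolution maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .errors import ModelError

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "Model",
    "read_model",
    "write_model",
    "classify_residue",
    "select_score_atoms",
    "write_model_with_scores",
    "PROTEIN_RESIDUES",
    "NUCLEIC_RESIDUES",
    "WATER_RESIDUES",
    "PROTEIN_SCORE_ATOMS",
    "NUCLEIC_SCORE_ATOMS",
]

PROTEIN_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE""".split()
)
NUCLEIC_RESIDUES = frozenset("A C G U T DA DC DG DT DU".split())
WATER_RESIDUES = frozenset({"HOH", "WAT"})

#: protein backbone atoms entering the score (carbonyl O deliberately absent)
PROTEIN_SCORE_ATOMS = ("N", "CA", "C")
#: nucleic-acid backbone atoms entering the score
NUCLEIC_SCORE_ATOMS = ("C1'", "C2'", "C3'", "C4'", "C5'", "O3'", "O4'", "O5'", "P")

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


@dataclass
class AtomRecord:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) world Å
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ModelError(f"non-finite position for atom {self.atom_name}")
        if not self.atom_name:
            raise ModelError("atom_name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    category: str = "ligand"  # protein | nucleic | ligand | water

    @property
    def id(self) -> tuple[str, int, str]:
        """Identity used everywhere: (chain, number, insertion code)."""
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.number}{self.insertion_code}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Model:
    chains: list[Chain] = field(default_factory=list)
    format: str = "pdb"  # 'pdb' or 'cif'; outputs mirror the input format
    name: str = "model"

    def residues(self):
        for chain in self.chains:
            yield from chain.residues

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def copy(self) -> "Model":
        return Model(
            chains=[
                Chain(c.id, [replace(r, atoms=[replace(a) for a in r.atoms]) for r in c.residues])
                for c in self.chains
            ],
            format=self.format,
            name=self.name,
        )


def _normalize_atom_name(name: str) -> str:
    # accept both prime and asterisk conventions for sugar atoms
    return name.strip().upper().replace("*", "'")


def classify_residue(residue_name: str, atom_names=None) -> str:
    """Category of a residue name: protein, nucleic, water or ligand.

    Total and deterministic; unknown names fall back to ``ligand``.  When
    ``atom_names`` is given, a non-standard residue whose atoms cover at
    least five of the nine nucleic backbone atoms is promoted to
    ``nucleic`` (common modified nucleotides, without a chemical
    dictionary).
    """
    name = residue_name.strip().upper()
    if name in PROTEIN_RESIDUES:
        return "protein"
    if name in NUCLEIC_RESIDUES:
        return "nucleic"
    if name in WATER_RESIDUES:
        return "water"
    if atom_names:
        normalized = {_normalize_atom_name(a) for a in atom_names}
        if len(normalized & set(NUCLEIC_SCORE_ATOMS)) >= 5:
            return "nucleic"
    return "ligand"


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties → first."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        key = a.atom_name
        if key not in best:
            best[key] = a
            order.append(key)
        elif a.occupancy > best[key].occupancy:
            best[key] = a
    return [best[k] for k in order]


def read_model(path: str | Path) -> Model:
    """Read a PDB or mmCIF model (auto-detected), file order preserved.

    Alternative locations are collapsed to the highest-occupancy conformer;
    hydrogens are retained (they are excluded later at atom selection).
    Only the first model of multi-model files is used.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ModelError(f"cannot parse model file {path}: {exc}") from exc
    if len(st) == 0:
        raise ModelError(f"{path}: file contains no model")
    st.setup_entities()
    fmt = "cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"

    model = Model(format=fmt, name=path.stem)
    gmodel = st[0]
    for gchain in gmodel:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            atoms = []
            for ga in gres:
                atoms.append(
                    AtomRecord(
                        chain_id=gchain.name,
                        residue_number=gres.seqid.num,
                        insertion_code=icode,
                        residue_name=gres.name,
                        atom_name=ga.name,
                        element=ga.element.name,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=float(ga.occ),
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                        b_factor=float(ga.b_iso),
                    )
                )
            atoms = _collapse_altlocs(atoms)
            chain.residues.append(
                Residue(
                    chain_id=gchain.name,
                    number=gres.seqid.num,
                    insertion_code=icode,
                    name=gres.name,
                    atoms=atoms,
                    category=classify_residue(gres.name, [a.atom_name for a in atoms]),
                )
            )
        if chain.residues:
            model.chains.append(chain)
    if model.n_residues == 0:
        raise ModelError(f"{path}: model contains no residues")
    n_h = sum(1 for r in model.residues() for a in r.atoms if a.is_hydrogen)
    if n_h:
        logger.info("%s: %d hydrogen atoms retained (excluded from scoring)", path.name, n_h)
    return model


def _to_gemmi(model: Model) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.name
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.atom_name
                ga.element = gemmi.Element(a.element or "X")
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                ga.altloc = a.altloc or "\x00"
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: Model, path: str | Path) -> None:
    """Write a model as PDB or mmCIF, chosen by the file extension."""
    path = Path(path)
    st = _to_gemmi(model)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def select_score_atoms(residue: Residue, mode: str = "backbone") -> list[AtomRecord]:
    """Atoms of a residue that enter the fit score.

    backbone mode — protein: N, CA, C (no carbonyl O); nucleic: the nine
    sugar-phosphate atoms; ligand/water: all atoms.  ca_only mode — protein:
    CA; nucleic: C1'; ligand/water: all atoms.  Hydrogens are never
    returned; missing atoms are silently omitted.
    """
    if mode not in ("backbone", "ca_only"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    heavy = [a for a in residue.atoms if not a.is_hydrogen]
    if residue.category in ("ligand", "water"):
        return heavy
    if residue.category == "protein":
        wanted = PROTEIN_SCORE_ATOMS if mode == "backbone" else ("CA",)
    else:  # nucleic
        wanted = NUCLEIC_SCORE_ATOMS if mode == "backbone" else ("C1'",)
    by_name = {_normalize_atom_name(a.atom_name): a for a in heavy}
    return [by_name[n] for n in wanted if n in by_name]


def write_model_with_scores(model: Model, residue_scores, path: str | Path) -> None:
    """Write the model with every atom's B-factor replaced by its residue's
    aggregate confidence score (missing/unscored → 0.0).

    ``residue_scores`` maps residue identity (chain, number, icode) → score,
    or is an iterable of objects with ``.id``/``.residue_id`` and ``.score``.
    """
    if not isinstance(residue_scores, dict):
        residue_scores = {
            getattr(s, "residue_id", getattr(s, "id", None)): s.score for s in residue_scores
        }
    out = model.copy()
    for res in out.residues():
        score = residue_scores.get(res.id)
        b = float(score) if score is not None else 0.0
        for a in res.atoms:
            a.b_factor = round(b, 2)
    write_model(out, path)
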