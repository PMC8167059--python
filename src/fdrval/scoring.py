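"""Per-residue backbone fit scores against a confidence map.

Each scored atom is associated with the voxels whose centers lie within the
association radius (1 Å by default) of its coordinate; the atom score is an
aggregate over those voxels (maximum by default — "is there any molecular
signal at this atom" — with mean and nearest-voxel alternatives for
sensitivity analysis).  The residue score is the arithmetic mean of its
selected atoms' scores: N/Cα/C for proteins, the sugar-phosphate backbone
for nucleic acids, all heavy atoms for ligands and waters.

Scores live in [0, 1] when the map is a confidence map; a residue fully in
background scores near 0, one fully supported by signal scores near 1.
Per-chain z-scores are advisory only — most residues score 1.0, so the score
distribution is far from normal and absolute values are the reliable signal.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .map_io import DensityMap, is_inside_grid, nearest_voxel, voxels_within_radius
from .model_io import Model, Residue, select_score_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringConfig",
    "ResidueScore",
    "atom_score",
    "residue_score",
    "score_model",
    "chain_zscores",
    "write_scores_csv",
    "write_chimera_attributes",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Atom-to-map association and aggregation settings.

    association_radius : Å radius of the voxel neighborhood around each atom
        (default 1.0).
    mode : 'backbone' (default) or 'ca_only'.
    aggregation : 'max' (default), 'mean' or 'nearest' over the neighborhood.
    """

    association_radius: float = 1.0
    mode: str = "backbone"
    aggregation: str = "max"

    def __post_init__(self) -> None:
        if self.association_radius <= 0:
            raise ValueError("association_radius must be > 0")
        if self.mode not in ("backbone", "ca_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.aggregation not in ("max", "mean", "nearest"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class ResidueScore:
    """Per-residue scoring record."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    category: str
    atom_scores: dict[str, float] = field(default_factory=dict)
    score: float | None = None
    n_atoms_scored: int = 0
    z_score: float | None = None
    out_of_grid: bool = False

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}{self.insertion_code}"


def _atom_score(dmap: DensityMap, position, config: ScoringConfig) -> tuple[float, bool]:
    if not is_inside_grid(dmap, position):
        return 0.0, True
    voxels = voxels_within_radius(dmap, position, config.association_radius)
    if not voxels:
        idx = nearest_voxel(dmap, position)
        return float(dmap.values[idx]), False
    vals = np.array([dmap.values[v] for v in voxels])
    if config.aggregation == "max":
        return float(vals.max()), False
    if config.aggregation == "mean":
        return float(vals.mean()), False
    # nearest: voxel center closest to the atom
    centers = dmap.origin + np.asarray(voxels) * dmap.voxel_size
    d2 = np.sum((centers - np.asarray(position, dtype=float)) ** 2, axis=1)
    return float(vals[int(np.argmin(d2))]), False


def atom_score(dmap: DensityMap, position, config: ScoringConfig | None = None) -> float:
    """Map value associated with an atom position.

    Aggregates over the voxels within the association radius; an in-grid
    position with no voxel center inside the radius falls back to the
    nearest voxel; a position outside the grid scores 0.0.
    """
    value, _ = _atom_score(dmap, position, config or ScoringConfig())
    return value


def residue_score(
    dmap: DensityMap, residue: Residue, config: ScoringConfig | None = None
) -> ResidueScore:
    """Score one residue: mean of its selected atoms' map values."""
    config = config or ScoringConfig()
    record = ResidueScore(
        chain_id=residue.chain_id,
        residue_number=residue.number,
        insertion_code=residue.insertion_code,
        residue_name=residue.name,
        category=residue.category,
    )
    atoms = select_score_atoms(residue, config.mode)
    values = []
    for a in atoms:
        v, outside = _atom_score(dmap, a.position, config)
        record.atom_scores[a.atom_name] = v
        record.out_of_grid = record.out_of_grid or outside
        values.append(v)
    if values:
        record.score = float(np.mean(values))
        record.n_atoms_scored = len(values)
    return record


def score_model(
    dmap: DensityMap, model: Model, config: ScoringConfig | None = None
) -> list[ResidueScore]:
    """Score every residue of a model, file order preserved.

    Works on any map; when the values fall outside [0, 1] (i.e. not a
    confidence map) a warning is logged and raw values are reported
    unclamped.
    """
    config = config or ScoringConfig()
    vmin, vmax = float(dmap.values.min()), float(dmap.values.max())
    if vmin < 0.0 or vmax > 1.0:
        logger.warning(
            "map values span [%.3g, %.3g] — not a confidence map; "
            "reporting raw map values unclamped",
            vmin,
            vmax,
        )
    scores = [residue_score(dmap, res, config) for res in model.residues()]
    n_out = sum(1 for s in scores if s.out_of_grid)
    if n_out:
        logger.warning("%d residues have atoms outside the map grid (scored 0.0)", n_out)
    return scores


def chain_zscores(scores: list[ResidueScore], ddof: int = 1) -> list[ResidueScore]:
    """Fill per-chain z-scores in place (and return the list).

    z = (score − chain mean) / chain sd over the chain's scored polymer and
    ligand residues; waters are excluded from the statistics and receive no
    z-score.  Chains with fewer than two scored residues or zero sd get
    z = 0 everywhere.
    """
    by_chain: dict[str, list[ResidueScore]] = {}
    for s in scores:
        if s.score is not None and s.category != "water":
            by_chain.setdefault(s.chain_id, []).append(s)
    for members in by_chain.values():
        vals = np.array([s.score for s in members])
        if len(vals) < 2:
            for s in members:
                s.z_score = 0.0
            continue
        sd = float(np.std(vals, ddof=ddof))
        mean = float(np.mean(vals))
        for s in members:
            s.z_score = 0.0 if sd == 0.0 else float((s.score - mean) / sd)
    return scores


def write_scores_csv(scores: list[ResidueScore], path) -> None:
    """Write one CSV row per residue (scores to 3 decimals)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "chain",
                "residue_number",
                "insertion_code",
                "residue_name",
                "category",
                "n_atoms_scored",
                "score",
                "z_score",
            ]
        )
        for s in scores:
            w.writerow(
                [
                    s.chain_id,
                    s.residue_number,
                    s.insertion_code,
                    s.residue_name,
                    s.category,
                    s.n_atoms_scored,
                    "" if s.score is None else f"{s.score:.3f}",
                    "" if s.z_score is None else f"{s.z_score:.3f}",
                ]
            )


_ATTR_NAME_RE = re.compile(r"^[a-z][A-Za-z0-9_]*$")


def write_chimera_attributes(
    scores: list[ResidueScore], attribute_name: str, path
) -> None:
    """Write a UCSF Chimera ``defattr`` residue-attribute file.

    One tab-indented line per scored residue:
    ``\\t:<resnum><icode>.<chain>\\t<score>`` under the standard
    attribute/match mode/recipient header.  The attribute name must start
    with a lowercase letter (defattr grammar).
    """
    if not _ATTR_NAME_RE.match(attribute_name):
        raise ValueError(
            f"invalid attribute name {attribute_name!r}: must start with a "
            "lowercase letter and contain only letters, digits and underscores"
        )
    with open(path, "w") as fh:
        fh.write(f"attribute: {attribute_name}\n")
        fh.write("match mode: 1-to-1\n")
        fh.write("recipient: residues\n")
        for s in scores:
            if s.score is None:
                continue
            fh.write(f"\t:{s.residue_number}{s.insertion_code}.{s.chain_id}\t{s.score:.3f}\n")
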