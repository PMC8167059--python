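"""Shared fixtures and independent reference oracles."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from fdrval.map_io import DensityMap, write_density_map
from fdrval.model_io import AtomRecord, Chain, Model, Residue
from fdrval.scoring import ResidueScore
from fdrval.synthetic import make_scene


@pytest.fixture(scope="session")
def scene_snr5():
    """A clean 12-residue scene at SNR 5 (no mistraces), fixed seed."""
    return make_scene(seed=11)


@pytest.fixture
def random_map():
    rng = np.random.default_rng(42)
    return DensityMap(
        values=rng.normal(size=(12, 14, 16)),
        voxel_size=(1.0, 1.0, 1.0),
        origin=(0.0, 0.0, 0.0),
    )


def write_permuted_mrc(dmap: DensityMap, path, perm=(2, 1, 3)) -> None:
    """Write an MRC file storing the same physical volume with permuted
    storage axes (mapc, mapr, maps) = ``perm``.

    Independent of the reader under test: the file is produced by writing
    the canonical file and then patching the header words and re-laying the
    data section with a plain numpy transpose.
    """
    write_density_map(dmap, path)
    raw = bytearray(open(path, "rb").read())
    dims = dmap.dims
    nc, nr, ns = (dims[perm[0] - 1], dims[perm[1] - 1], dims[perm[2] - 1])
    struct.pack_into("<3i", raw, 0, nc, nr, ns)
    struct.pack_into("<3i", raw, 64, *perm)
    # data section: sections vary slowest, columns fastest
    data = dmap.values.astype("<f4").transpose(perm[2] - 1, perm[1] - 1, perm[0] - 1)
    raw[1024:] = np.ascontiguousarray(data).tobytes()
    open(path, "wb").write(bytes(raw))


def brute_force_fdr(p, method: str) -> np.ndarray:
    """O(m^2) step-up reference: q_(i) = min over j >= i of p_(j)*m*c/j."""
    p = np.asarray(p, dtype=np.float64)
    m = p.size
    # the harmonic constant is shared with the implementation and computed
    # with the same (numpy pairwise) summation so that the bitwise check
    # exercises the step-up logic, not float summation order
    c = float(np.sum(1.0 / np.arange(1, m + 1))) if method == "by" else 1.0
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos_i in range(m):
        candidates = [p[order[pos_j]] * m * c / (pos_j + 1) for pos_j in range(pos_i, m)]
        q[order[pos_i]] = min(1.0, min(candidates))
    return q


def brute_force_voxels_within_radius(dmap: DensityMap, coord, radius):
    """Full-grid scan reference for the voxel-neighborhood query."""
    coord = np.asarray(coord, dtype=float)
    out = []
    nx, ny, nz = dmap.dims
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                center = dmap.origin + np.array([i, j, k]) * dmap.voxel_size
                if np.sum((center - coord) ** 2) <= radius * radius:
                    out.append((i, j, k))
    return out


def make_scored_chain(scores_by_number, chain_id="A", category="protein", start_number=1):
    """A minimal model + ResidueScore list from {residue_number: score}.

    Residues are single-CA placeholders; geometry is irrelevant to pruning
    and z-score logic.
    """
    chain = Chain(id=chain_id)
    records = []
    for num in sorted(scores_by_number):
        atom = AtomRecord(
            chain_id=chain_id,
            residue_number=num,
            insertion_code="",
            residue_name="ALA" if category == "protein" else "LIG",
            atom_name="CA",
            element="C",
            position=np.array([float(num), 0.0, 0.0]),
        )
        chain.residues.append(
            Residue(
                chain_id=chain_id,
                number=num,
                insertion_code="",
                name=atom.residue_name,
                atoms=[atom],
                category=category,
            )
        )
        records.append(
            ResidueScore(
                chain_id=chain_id,
                residue_number=num,
                insertion_code="",
                residue_name=atom.residue_name,
                category=category,
                atom_scores={"CA": scores_by_number[num]},
                score=scores_by_number[num],
                n_atoms_scored=1,
            )
        )
    return Model(chains=[chain]), records


def constant_neighborhood_map(atom_values, spacing=5.0, box=16):
    """A confidence-valued grid where each listed atom sits in its own
    region of constant value: positions x = 3, 3+spacing, ... on the
    central row, with a 2 Å ball around each set to the requested value.

    Returns (DensityMap, [positions]).  Used to drive the per-residue
    aggregation with chosen per-atom confidences through the real scoring
    path.
    """
    values = np.zeros((box, box, box))
    dmap = DensityMap(values=values, voxel_size=1.0, origin=(0.0, 0.0, 0.0))
    mid = box // 2
    positions = []
    for i, val in enumerate(atom_values):
        pos = np.array([3.0 + i * spacing, float(mid), float(mid)])
        positions.append(pos)
        idx = np.rint(pos).astype(int)
        sl = tuple(slice(max(c - 2, 0), c + 3) for c in idx)
        gx, gy, gz = np.meshgrid(
            *[np.arange(s.start, s.stop) for s in sl], indexing="ij"
        )
        d2 = (gx - pos[0]) ** 2 + (gy - pos[1]) ** 2 + (gz - pos[2]) ** 2
        region = values[sl]
        region[d2 <= 4.0] = val
        values[sl] = region
    return dmap, positions


def backbone_residue_at(positions, number=1, chain_id="A"):
    """A protein residue whose N, CA, C sit at the three given positions
    (plus a carbonyl O duplicated on the last position, which scoring must
    ignore)."""
    names = ["N", "CA", "C"]
    atoms = [
        AtomRecord(
            chain_id=chain_id,
            residue_number=number,
            insertion_code="",
            residue_name="VAL",
            atom_name=name,
            element=name[0],
            position=np.asarray(pos, dtype=float),
        )
        for name, pos in zip(names, positions)
    ]
    atoms.append(
        AtomRecord(
            chain_id=chain_id,
            residue_number=number,
            insertion_code="",
            residue_name="VAL",
            atom_name="O",
            element="O",
            position=np.asarray(positions[-1], dtype=float) + np.array([0.0, 1.2, 0.0]),
        )
    )
    return Residue(
        chain_id=chain_id,
        number=number,
        insertion_code="",
        name="VAL",
        atoms=atoms,
        category="protein",
    )
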