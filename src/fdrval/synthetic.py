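"""Self-contained synthetic test scenes.

A scene is a toy poly-alanine-like chain rendered as a sum of spherical
Gaussian atoms on a voxel grid, embedded in i.i.d. Gaussian background
noise, together with the ground-truth signal mask (voxels within 2.5 atom
sigmas of any true atom).  Deliberate "mistraces" are produced by rigidly
displacing chosen residues into the background while the density is still
rendered from the true positions — exactly the failure mode per-residue
confidence scoring is meant to catch.

SNR is defined as peak atom amplitude / background noise sd; presets at
3/5/10 loosely emulate poor/typical/good local map quality.  Gaussian atoms
(not electron form factors) are deliberate: they exercise the statistics,
not resolution realism.  All randomness flows through one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .map_io import DensityMap
from .model_io import AtomRecord, Chain, Model, Residue

__all__ = [
    "SyntheticScene",
    "make_toy_chain",
    "render_map",
    "add_noise",
    "displace_residues",
    "make_scene",
]

#: consecutive Cα spacing along the chain direction, Å
CA_SPACING = 3.8
#: N and C offsets from Cα along the chain axis, Å
N_OFFSET = 1.46
C_OFFSET = 1.52
#: carbonyl O offset from C, perpendicular to the chain axis, Å
O_OFFSET = 1.23
#: truth mask radius in units of the atom sigma
MASK_SIGMA_FACTOR = 2.5
#: required distance (voxels) between any atom and the nearest box face
BOX_MARGIN_VOXELS = 8


@dataclass
class SyntheticScene:
    """Toy model + map + ground truth for end-to-end testing.

    ``model`` is the model to score (it may contain displaced residues);
    ``true_model`` holds the in-density positions the map was rendered
    from.  ``truth_mask`` is True on voxels within 2.5 sigma of any true
    atom.
    """

    model: Model
    true_model: Model
    clean_map: DensityMap
    noisy_map: DensityMap
    truth_mask: np.ndarray
    sigma_atom: float
    amplitude: float
    noise_sd: float
    seed: int
    displaced_ids: tuple[tuple[str, int, str], ...] = ()

    @property
    def snr(self) -> float:
        return self.amplitude / self.noise_sd if self.noise_sd > 0 else float("inf")


def _perpendicular(direction: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, direction)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    perp = trial - np.dot(trial, direction) * direction
    return perp / np.linalg.norm(perp)


def make_toy_chain(
    n_residues: int,
    start=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    chain_id: str = "A",
) -> Model:
    """Extended poly-alanine-like backbone along a straight line.

    Consecutive Cα atoms are 3.8 Å apart along ``direction``; N and C sit
    1.46/1.52 Å before/after each Cα on the chain axis, and the carbonyl O
    1.23 Å perpendicular to it.  ``start`` is the first Cα position.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    d = d / norm
    perp = _perpendicular(d)
    start = np.asarray(start, dtype=float)

    chain = Chain(id=chain_id)
    for i in range(n_residues):
        num = i + 1
        ca = start + i * CA_SPACING * d
        positions = {
            "N": ca - N_OFFSET * d,
            "CA": ca,
            "C": ca + C_OFFSET * d,
            "O": ca + C_OFFSET * d + O_OFFSET * perp,
        }
        atoms = [
            AtomRecord(
                chain_id=chain_id,
                residue_number=num,
                insertion_code="",
                residue_name="ALA",
                atom_name=name,
                element=name[0],
                position=pos,
            )
            for name, pos in positions.items()
        ]
        chain.residues.append(
            Residue(
                chain_id=chain_id,
                number=num,
                insertion_code="",
                name="ALA",
                atoms=atoms,
                category="protein",
            )
        )
    return Model(chains=[chain], format="pdb", name=f"toy{n_residues}")


def render_map(
    model: Model,
    voxel_size: float = 1.0,
    box_dims=(64, 64, 64),
    sigma_atom: float = 1.0,
    amplitude: float = 1.0,
    origin=(0.0, 0.0, 0.0),
) -> tuple[DensityMap, np.ndarray]:
    """Render Gaussian-atom density and its ground-truth mask.

    Each non-hydrogen atom contributes amplitude·exp(−d²/(2σ²)) summed over
    the grid (evaluated out to 4σ); the mask marks voxels within 2.5σ of
    any atom.  The model must keep an 8-voxel margin from every box face so
    the default noise cubes stay signal-free.
    """
    dims = np.broadcast_to(np.asarray(box_dims, dtype=int), (3,)).copy()
    origin = np.asarray(origin, dtype=float)
    vs = float(voxel_size)
    values = np.zeros(tuple(dims), dtype=np.float64)
    mask = np.zeros(tuple(dims), dtype=bool)

    margin = BOX_MARGIN_VOXELS * vs
    lo_bound = origin + margin
    hi_bound = origin + (dims - 1) * vs - margin

    reach = 4.0 * sigma_atom
    mask_radius = MASK_SIGMA_FACTOR * sigma_atom
    for res in model.residues():
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            pos = atom.position
            if np.any(pos < lo_bound) or np.any(pos > hi_bound):
                raise ConfigurationError(
                    f"atom {atom.atom_name} of {res.label} at {np.round(pos, 1)} "
                    f"violates the {BOX_MARGIN_VOXELS}-voxel box margin"
                )
            frac = (pos - origin) / vs
            lo = np.maximum(np.ceil(frac - reach / vs).astype(int), 0)
            hi = np.minimum(np.floor(frac + reach / vs).astype(int), dims - 1)
            sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
            gx, gy, gz = np.meshgrid(
                np.arange(lo[0], hi[0] + 1),
                np.arange(lo[1], hi[1] + 1),
                np.arange(lo[2], hi[2] + 1),
                indexing="ij",
            )
            d2 = (
                (origin[0] + gx * vs - pos[0]) ** 2
                + (origin[1] + gy * vs - pos[1]) ** 2
                + (origin[2] + gz * vs - pos[2]) ** 2
            )
            values[sl] += amplitude * np.exp(-d2 / (2.0 * sigma_atom**2))
            mask[sl] |= d2 <= mask_radius**2
    dmap = DensityMap(values=values, voxel_size=np.full(3, vs), origin=origin, label="synthetic")
    return dmap, mask


def add_noise(dmap: DensityMap, noise_sd: float, seed) -> DensityMap:
    """Add i.i.d. Gaussian background noise (reproducible given the seed)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return dmap.with_values(dmap.values.copy())
    rng = np.random.default_rng(seed)
    return dmap.with_values(dmap.values + rng.normal(0.0, noise_sd, size=dmap.dims))


def displace_residues(model: Model, residue_ids, offset) -> Model:
    """Copy of the model with the listed residues rigidly translated.

    ``residue_ids`` may be (chain, number, icode) triples or bare residue
    numbers (matched in any chain).  All other residues are untouched.
    """
    offset = np.asarray(offset, dtype=float)
    wanted = set()
    numbers = set()
    for rid in residue_ids:
        if isinstance(rid, tuple):
            wanted.add(rid)
        else:
            numbers.add(int(rid))
    out = model.copy()
    for res in out.residues():
        if res.id in wanted or res.number in numbers:
            for a in res.atoms:
                a.position = a.position + offset
    return out


def make_scene(
    n_residues: int = 12,
    snr: float = 5.0,
    box_dims=(64, 64, 64),
    voxel_size: float = 1.0,
    sigma_atom: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    displaced_residues=(),
    displacement=(8.0, 0.0, 0.0),
) -> SyntheticScene:
    """Build a complete scene: chain along z, centered in the box.

    The map is rendered from the true (in-density) chain; the scene's
    ``model`` has ``displaced_residues`` (residue numbers) rigidly shifted
    by ``displacement`` (default 8 Å along +x, well outside the truth
    mask).  Amplitude is snr × noise_sd.
    """
    dims = np.broadcast_to(np.asarray(box_dims, dtype=int), (3,)).copy()
    extent = (dims - 1) * voxel_size
    span = (n_residues - 1) * CA_SPACING
    center_xy = extent / 2.0
    start = np.array([center_xy[0], center_xy[1], (extent[2] - span) / 2.0])
    true_model = make_toy_chain(n_residues, start=start, direction=(0, 0, 1))

    amplitude = snr * noise_sd
    clean, mask = render_map(
        true_model,
        voxel_size=voxel_size,
        box_dims=dims,
        sigma_atom=sigma_atom,
        amplitude=amplitude,
    )
    noisy = add_noise(clean, noise_sd, seed)
    model = (
        displace_residues(true_model, displaced_residues, displacement)
        if displaced_residues
        else true_model.copy()
    )
    displaced_ids = tuple(
        res.id for res in model.residues() if res.number in {int(r) for r in displaced_residues}
    )
    return SyntheticScene(
        model=model,
        true_model=true_model,
        clean_map=clean,
        noisy_map=noisy,
        truth_mask=mask,
        sigma_atom=sigma_atom,
        amplitude=amplitude,
        noise_sd=noise_sd,
        seed=seed if isinstance(seed, int) else 0,
        displaced_ids=displaced_ids,
    )
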