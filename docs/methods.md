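# Methods

## Statistical model

The background of a sharpened, unmasked cryo-EM reconstruction is modelled
as i.i.d. Gaussian noise N(μ, σ²), with μ and σ estimated by pooling the
voxels of four cubes placed outside the particle. Each voxel is tested
against this null with a one-sided (right-tailed) test — molecular signal
is positive density after sharpening — giving p = 1 − Φ((v − μ)/σ). The
test is parametric on purpose: it makes p, and hence the confidence,
strictly monotone in the raw voxel value, so thresholding the confidence
map is equivalent to an intensity threshold with a statistical calibration.

Voxel-wise p-values are adjusted with the Benjamini–Yekutieli (BY) step-up
procedure. Reconstructed voxels are strongly spatially correlated, and BY
controls the FDR under arbitrary dependence at the price of the harmonic
factor c(m) = Σ 1/k (≈ 13 for a 64³ grid). Benjamini–Hochberg (BH) is
offered for sensitivity analysis; BY q-values dominate BH q-values
elementwise, so BY is the conservative default. The confidence is
c = 1 − q. Monotonicity of q in p is enforced by a running minimum from the
largest p downwards; all p-values are floored at the smallest positive
double so the input contract p ∈ (0, 1] always holds.

Degenerate backgrounds (σ = 0, e.g. masked or solvent-flattened maps) are a
hard error: with the background removed there is no null to estimate, and
any answer would be arbitrary.

## Noise-cube placement

The four default cubes sit at the −x, +x, −y, +y face midpoints, pushed
against the box faces, and must lie entirely outside a central guard sphere
of radius `guard_fraction` (default 0.35) × the smallest box extent. The
default cube edge is the largest odd number ≤ 1/8 of the smallest grid
dimension (floor 5 voxels). Which four of the six axis-face positions carry
the cubes is a configurable convention; positions and edge can be
overridden. `check_noise_regions` screens each cube against the pooled
others (flag when the mean exceeds them by more than k = 5 standard errors)
so a cube accidentally covering molecular signal is reported before it
biases the null.

## Atom association and residue aggregation

An atom is associated with all voxels whose *centers* lie within the
association radius (default 1 Å, Euclidean distance in Å, anisotropic
voxels supported) of its coordinate; the atom score is the **maximum**
confidence in that neighborhood. Maximum answers "is there any molecular
signal at this atom" and is robust for atoms near contour edges; `mean` and
`nearest` aggregations are available for sensitivity analysis, and
empirically they are markedly less reliable at separating in-density from
displaced residues on synthetic scenes. An in-grid atom whose neighborhood
contains no voxel center (coarse grids) falls back to the nearest voxel; an
atom outside the grid scores 0.0 and is flagged rather than raising —
models routinely overhang trimmed boxes.

The residue score is the arithmetic mean of its selected atoms: N/Cα/C for
proteins (no carbonyl O), the nine sugar-phosphate backbone atoms for
nucleic acids, all heavy atoms for ligands and waters. Hydrogens are never
scored. Per-chain z-scores are provided but advisory: most residues score
1.0, the distribution is far from normal, and absolute scores are the
reliable signal. Waters are excluded from the z-score statistics. Reported
precision: three decimals in the CSV and Chimera attribute file, two in the
PDB B-factor column (format limit); values are rounded, not truncated.

## Pruning

Residues with score < τ (default 0.9) are removed together with `flank`
(default 1) neighbors on each side. Adjacency is position in the chain's
file-order residue list, not residue-number arithmetic — robust to
insertion codes and numbering gaps; windows never cross chains and are
truncated at chain ends. Ligands and waters have no chemically meaningful
flank and are removed alone. Unscored residues are retained. Pruning is not
idempotent in general (a flanking residue may itself score ≥ τ), but
re-pruning a pruned model with the same scores removes nothing.

## File-format conventions

MRC2014 volumes are read and written through gemmi; storage-axis
permutations (mapc/mapr/maps), nstart and the ORIGIN record are honored,
and grids are normalised to X,Y,Z order in memory, so all downstream
results are invariant to the file's storage order. The origin is taken from
the ORIGIN record when nonzero, else nstart × voxel size, and refers to the
center of voxel (0,0,0). Values are processed in float64 and written back
as mode-2 float32. Models are read/written with gemmi (PDB and mmCIF);
alternative locations collapse to the highest-occupancy conformer (ties:
first in file); prime and asterisk sugar-atom spellings (C1′/C1*) are both
accepted; insertion codes are part of residue identity everywhere.
Non-standard residues whose atoms cover ≥ 5 of the 9 nucleic backbone
atoms are treated as nucleotides; everything else unknown is a ligand.

## Synthetic scenes

The generator emulates the statistical structure the method relies on — a
compact region of positive signal in an i.i.d. Gaussian background with a
known truth mask — not cryo-EM image formation. Atoms are spherical
Gaussians (σ = 1 Å by default), amplitude = SNR × noise sd (SNR presets
3/5/10 ≈ poor/typical/good local quality, default 5, noise sd 1). The
default scene is a 12-residue straight chain along z, centered in a 64³,
1 Å-voxel box — the longest straight chain that keeps an 8-voxel margin to
every face, which in turn keeps the default ±x/±y noise cubes clear of the
truth mask (within 2.5 σ of any atom). Longer chains need a larger box.
Real maps have correlated noise, B-factor falloff, CTF effects and masking
artifacts that the generator deliberately omits; passing tests demonstrate
the statistical machinery (FDR calibration, scoring, pruning), not
performance on experimental data.

## Problem sizes and known limitations

The test suite and the reproduction script use 48³–64³ grids and 20-scene
ensembles; at these sizes the full pipeline runs in seconds per scene.

Two tail effects are worth knowing. First, FDR control at 1% *admits* up to
1% background voxels among discoveries; with ~8000 signal voxels per scene,
a handful of top-tail noise voxels are legitimately assigned high
confidence, and roughly once per ~120 displaced residues one of them falls
within 1 Å of a displaced atom, lifting that residue's score above ~0.1
(though still far below the 0.9 pruning threshold). Second, a terminal
residue's N atom has the weakest density coverage and can dip just below
0.99 under an adverse noise draw at SNR 5. Both are properties of the
statistic, not defects: mistraces remain cleanly separated from in-density
residues at the 0.9 pruning threshold in every scene examined.

The score validates backbone placement only; side-chain rotamer errors are
out of scope, as are local resolution estimation, sharpening, and the
comparison metrics (Q-score, SMOC, SCCC, CCC, FSC-Q) the score complements.
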