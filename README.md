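# fdrval

Per-residue backbone validation of cryo-EM atomic models with
false-discovery-rate confidence maps.

## The problem

Cryo-EM maps have spatially varying quality: resolution is usually best in
the core of a molecular assembly and degrades towards flexible or partially
occupied regions. Automated model-building tools can trace parts of a chain
into background noise ("mistraces"), and global map-model scores do not
localise these errors. `fdrval` scores *each residue* of a model by the
statistical confidence that its backbone atoms sit in molecular signal
rather than background, and can automatically prune low-confidence residues
so that iterative building tools can rebuild those segments.

## The method

1. **Background estimate.** Four small cubes placed outside the particle
   (near the box faces on the central axes) provide a pooled Gaussian null
   N(μ, σ²) for the background intensity of a sharpened, *unmasked* map.
   Masked maps have no background left and are rejected.
2. **Voxel-wise testing.** Every voxel value v gets a right-tailed p-value
   p = 1 − Φ((v − μ)/σ).
3. **FDR adjustment.** The p-values are adjusted with the
   Benjamini–Yekutieli step-up procedure (valid under arbitrary dependence;
   Benjamini–Hochberg available as an option):
   q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎ · m · c(m) / j with c(m) = Σ_{k≤m} 1/k.
   The **confidence map** is c = 1 − q ∈ [0, 1]; thresholding it at 0.99
   bounds the expected fraction of background voxels among the selected
   ones at 1%.
4. **Residue scoring.** Each atom is associated with the maximum confidence
   among voxels within 1 Å of its coordinate. The *FDR backbone score* of a
   residue is the mean over its N, Cα and C atoms (the carbonyl O is
   excluded — its density is weak below ~3 Å resolution); for nucleotides,
   over C1′–C5′, O3′, O4′, O5′ and P; for ligands and waters, over all
   heavy atoms. A Cα-only mode (C1′ for nucleic acids) supports backbone-only
   models. Scores below 0.95 deserve attention; below 0.9 usually indicates
   a clear mistrace.
5. **Pruning.** Residues scoring below 0.9 are removed together with their
   immediate chain neighbors, yielding a `*_pruned` model for the next
   building round.

## Worked example

Generate a synthetic scene — a 12-residue chain rendered as Gaussian atoms
in Gaussian noise (SNR 5) with residues 6–8 deliberately displaced 8 Å into
background — then validate and prune:

```sh
fdrval simulate --out scene --seed 51 --displace 6,7,8
fdrval validate --map scene/scene.mrc --model scene/scene.pdb --out results --prune
```

prints

```
12 residues scored: 3 below 0.95 (need attention), 3 below 0.90 (likely mistraced)
pruned model: 5 residues removed
```

The three displaced residues score ~0.0 while all in-density residues score
1.0 (`results/scene_scores.csv`); the pruned model drops residues 5–9: the
three mistraces plus one flanking neighbor on each side
(`results/scene_removed.txt` lists each with its reason). Other outputs:
`scene.defattr` (UCSF Chimera residue attribute for coloring),
`scene_bfactor.pdb` (B-factor column replaced by the scores). A confidence
map alone can be computed with `fdrval confmap --map … --out conf.mrc`.

Python API: `fdrval.confidence_map`, `fdrval.score_model`, `fdrval.prune`,
`fdrval.make_scene` mirror the CLI.

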