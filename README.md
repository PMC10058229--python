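# corepca

Ensemble Cα principal component analysis for detecting shared conformational
switches across protein superfamilies.

Cytoskeletal and cytomotive proteins — actins, tubulins, and their bacterial and
archaeal relatives — are sampled by hundreds of deposited structures in many
functional states. A recurring question is whether subunits adopt a discrete
conformational change upon polymerization (an assembly switch), and whether that
change tracks the hydrolysis state of the bound nucleotide. `corepca` answers
this quantitatively: it places every structure's residues into the column frame
of a master multiple sequence alignment, collapses redundant depositions into
representatives, finds the structurally invariant core, superposes everything on
it, and analyzes the remaining Cα variation by PCA and annotation-correlation
statistics.

## What it computes

Given structures mapped to a common set of L alignment columns and superposed on
the invariant core, each structure is a vector **x**ᵢ ∈ ℝ³ᴸ. PCA
eigendecomposes the covariance S = (n−1)⁻¹ Σᵢ (**x**ᵢ − **x̄**)(**x**ᵢ − **x̄**)ᵀ
into eigenvalues λ₁ ≥ λ₂ ≥ … (Å², the variance along each collective motion) and
orthonormal loadings (per-residue displacement patterns, renderable as
porcupine plots or morph trajectories). Scores zᵢₖ place each structure in PC
subspace. For an annotation with groups g, separation along PC k is
η² = SS_between/SS_total of the scores, calibrated by a seeded permutation
null. The invariant core itself is found by iteratively discarding the column
whose positional covariance ellipsoid volume (4/3)π√(λ₁λ₂λ₃) is largest until
the total remaining volume falls below a cutoff (default 0.5 Å³). Superposition
uses the closed-form least-squares (Kabsch) rotation; redundant depositions are
complete-linkage clustered at 1.0 Å Cα RMSD.

## Worked example

Generate a synthetic superfamily with a planted 15° assembly-state hinge and
run the full pipeline:

```sh
corepca simulate --outdir demo/data --seed 1
corepca run --manifest demo/data/manifest.tsv \
            --alignment demo/data/master_alignment.fasta \
            --outdir demo/out --seed 1
```

which prints (abridged):

```json
{
  "ingest": {"n_entries": 48},
  "representatives": {"n_groups": 20, "n_representatives": 20},
  "core": {"n_frame_columns": 68, "core_size": 8, "initial_volume": 49.9562},
  "pca": {"proportions": [0.94959, 0.011193, 0.005552, ...],
          "cumulative_pc1_2": 0.960783},
  "analyze": {"pc1_assembly_point_biserial_r": 0.998941,
              "separation": {"assembly_state": {"PC1": {"eta_sq": 0.997884,
                                                        "p_value": 0.0001}},
                             "nucleotide_state": {"PC1": {"eta_sq": 0.037173,
                                                          "p_value": 0.848}}}}
}
```

Reading: 48 generated entries collapse to 20 non-redundant representatives; the
common 100%-occupancy frame has 68 columns, of which 8 survive invariant-core
refinement at the 0.5 Å³ cutoff; PC1 carries ~95% of the Cα variance, is almost
perfectly correlated with the assembly state (r = 0.999, η² = 0.998, permutation
p = 1e-4) — the planted switch — while the nucleotide labels, drawn
independently of geometry, show no association (η² = 0.037, p = 0.85). Stage
outputs (cluster tables, core removal trace, eigenvalue/score/loading tables,
annotated score scatter data) are TSVs under `demo/out/`, and `report.json`
embeds the exact configuration for audit. `corepca morph` exports a PC
trajectory as a multi-model PDB for visualization.

The same pipeline runs unchanged on real data: point the manifest at deposited
PDB/mmCIF files (one chain per row, with subfamily/ligand/state annotations) and
the alignment at a superfamily master alignment.

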