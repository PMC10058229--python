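# Methods

`corepca` implements a comparative structural analysis for detecting shared
conformational switches — in particular, subunit conformational changes adopted
upon polymerization — across protein superfamilies such as the actins and
tubulins. The analysis operates on Cα coordinates of deposited structures placed
into the common column frame of a master multiple sequence alignment.

## The model and procedure

The central assumption is that homologous structures, once mapped onto a common
set of alignment columns and superposed on a structurally invariant core, differ
by a small number of collective linear displacements of their Cα atoms. Those
displacements are recovered as principal components of the fitted coordinate
covariance, and biological state labels (subfamily, nucleotide hydrolysis state,
assembly state) are then tested for association with position along each
component.

The stages are:

1. **Ingestion.** Each manifest row names one chain of a PDB/mmCIF file. Only Cα
   atoms are kept; alternate locations resolve to the highest-occupancy altloc
   (ties to the alphabetically first id); multi-model files contribute model 1
   only; author residue numbering and insertion codes are preserved as the
   residue key space. Nucleotide state is classified from the bound-ligand codes
   by a configurable table (ATP/GTP → NTP; non-hydrolyzable analogues such as
   GMPCPP/AMP-PNP → NTPa; ADP/GDP → NDP; nothing bound → apo) with precedence
   NTP > NTPa > NDP when several classes co-occur. Assembly state is taken from
   the manifest when declared; otherwise a heuristic marks filament/helical
   reconstructions as polymerized. Every assignment records its provenance.
2. **Column mapping.** The observed one-letter sequence is globally aligned
   against the ungapped sequence of the entry's own alignment row
   (match +2, mismatch −1, gap open −5, gap extend −1 — identity-style scores,
   since a sequence is being reconciled with its own row, not matched to a
   homolog). Unresolved residues and construct differences appear as gaps. An
   identity below 95% over the aligned region aborts the entry: in practice that
   always means the manifest points at the wrong chain or row.
3. **Redundancy clustering.** Entries with the same construct sequence
   (alignment-row sequence), nucleotide state, and assembly state are clustered
   by pairwise post-fit Cα RMSD with complete linkage cut at 1.0 Å, which bounds
   every cluster's diameter below the threshold. Each cluster contributes its
   highest-resolution member; ties fall to the most built residues, then the
   lexicographically first id; a manual override can force a different member
   and is flagged. The row sequence (not the observed sequence) keys the groups
   deliberately: observed sequences differ whenever a residue is unresolved,
   which would otherwise split replicate depositions of the same protein into
   singleton groups.
4. **Common frame and invariant core.** The analysis frame is the set of
   columns occupied by every representative (occupancy threshold configurable,
   default 1.0 — the strict "ungapped" intersection). The invariant core is
   found by iterated removal: superpose all representatives on the current
   column set by iterated mean fitting, compute each column's 3×3 positional
   covariance across entries (divisor n−1) and its ellipsoid volume
   (4/3)π√(λ₁λ₂λ₃) (negative eigenvalues clamped to 0), and discard the single
   largest-volume column (ties to the lowest index), until the total remaining
   volume is ≤ 0.5 Å³ or only 3 columns remain. One column per iteration keeps
   the removal trace canonical and deterministic.
5. **Core fitting and PCA.** All representatives are superposed on the core
   columns by iterated mean fitting (fit everything to entry 1, recompute the
   column-wise mean, refit to the mean, iterate to a 1e-6 Å mean-shift
   tolerance or 100 rounds); whole chains are transformed, not only the fit
   columns. PCA then runs over the *complete* column set (and, for audit, over
   the core columns as well — both variance tables are reported). Superposition
   is the closed-form least-squares rotation (SVD with reflection correction).
   Components are sign-fixed so the largest-magnitude loading element is
   positive, making scores reproducible across platforms.
6. **Annotation correlation.** For each PC and each annotation, the separation
   statistic is eta-squared (between-group / total score variance) with a
   seeded permutation null (default 9999 shuffles) — a quantitative surrogate
   for reading group separation off a score plot. Special/ambiguous entries
   are excluded from the statistic but kept in all exported tables. PC-vs-
   assembly association is additionally summarized as a point-biserial
   correlation. Fit-on-one-domain / report-on-another RMSD panels
   (`domain_aligned_rmsd`, `rmsd_matrix`) support per-domain comparisons,
   including concatenated chain pairs for heterodimers.

## Parameters that matter

| parameter | default | units | why |
| --- | --- | --- | --- |
| cluster threshold | 1.0 | Å | redundancy criterion: identically annotated structures within 1 Å are the same conformational snapshot |
| core volume cutoff | 0.5 | Å³ | total covariance-ellipsoid volume at which column removal stops; the reference convention for "invariant" |
| occupancy | 1.0 | fraction | strict column intersection; relaxable for sparse ensembles |
| identity gate | 0.95 | fraction | sequence/row reconciliation sanity check |
| permutations | 9999 | — | permutation-null resolution (p ≥ 1e-4) |
| trajectory amplitude / frames | ±2 SD / 15 | — | conventional morph range for visualizing a PC |

## The synthetic generator

Because the full analysis needs hundreds of downloaded structures, every stage
is exercised on generated ensembles with known ground truth. The generator
emulates the statistical structure the method is designed to detect: several
subfamilies sharing one fold (a smooth helical Cα curve, exact 3.8 Å spacing), a
two-state hinge rotation tied to the assembly-state label (the planted switch —
one geometric motif standing in for both inter-subdomain hinging and
interdomain rotation), one family-fixed deformation mode constructed orthogonal
(in 3L space) to the hinge mode so planted variance fractions are analytically
predictable, isotropic Gaussian coordinate noise, random rigid poses, occasional
unresolved residues, and family-specific insertions that become alignment
indels. Nucleotide labels are drawn independently of geometry, planting a true
null: any downstream nucleotide/conformation association is a false positive by
construction.

Default conditions: 3 families × 8 entries per (family, state) × 2 states
(48 entries), chain length 80 split at residue 40, hinge angles 0°/15°,
family-mode amplitude 1.0 Å, noise 0.3 Å, missing-residue rate 0.01. The chain
length and split give two toy "domains" with lever arms long enough that a 15°
hinge dominates the noise; amplitude 1.0 Å makes between-family scatter larger
than noise but far smaller than the switch; rate 0.01 keeps ≈60% of columns in
the strict 100%-occupancy frame at 48 entries. With 0.3 Å noise everywhere, the
0.5 Å³ cumulative cutoff reduces the invariant core to a handful of columns
(each noisy column contributes ≈0.11 Å³); this is the expected behavior of a
cumulative-volume criterion on uniformly noisy toy data, not a defect — real
structural cores have much lower scatter.

What the toys do **not** emulate: realistic protein geometry beyond Cα spacing,
side chains, ligand coordinates, correlated (anisotropic, B-factor-like) noise,
resolution-dependent error, or alignment errors. Passing tests therefore
demonstrate the correctness of the machinery and its statistical calibration,
not the biological conclusions obtainable from real depositions.

## Numerical choices and degenerate inputs

- Superposition requires ≥3 non-collinear points; degeneracy is detected via
  the second singular value of the cross-covariance.
- Reflection correction flips the sign of the smallest singular value, so the
  returned rotation always has determinant +1.
- Covariance divisors are n−1 throughout; per-column covariance eigenvalues are
  clamped at 0 before volumes are formed.
- Ties: equal column volumes remove the lowest column index; equal occupancy
  altlocs take the alphabetically first id; equal-resolution representatives
  fall to completeness, then id. All ties resolve deterministically.
- The PCA variance budget is exact (economy SVD), so Σλ equals the total
  centered variance to machine precision, and score covariance is diagonal
  with the eigenvalues on the diagonal.
- Coordinates written to PDB are fixed-width (1e-3 Å); zero-variance ensembles
  round-tripped through files therefore show eigenvalues at the ~1e-6 Å²
  quantization floor rather than exactly zero.

## Known limitations

- The pipeline treats the provided master alignment as ground truth; it does
  not build or correct alignments.
- "Ungapped positions" is implemented as an occupancy threshold over the
  representatives, so the common frame shrinks as more (or gappier) entries are
  added.
- The core-finding loop refits after every single-column removal; on very large
  ensembles a batch-removal variant would be faster but would no longer have a
  canonical trace.
- Structure-quality judgment beyond resolution and completeness (the basis for
  occasionally rejecting a representative by hand) is out of scope; the
  override hook is the mechanism for such decisions.
- `project()` re-superposes a model onto the PCA mean over the PCA columns;
  when the PCA columns differ from the fit columns (the default pipeline:
  PCA on complete columns, fit on the core) projected scores of ensemble
  members can differ from their stored scores by the small frame difference.
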