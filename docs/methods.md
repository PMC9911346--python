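# Methods

## Model and procedure

`homofill` transfers chemistry by homology: if an experimentally determined
structure shares a sufficiently similar sequence segment with a predicted
model, the binding sites inside that segment are assumed conserved enough
that a bound compound can be copied across after superposing the *local*
binding-site backbone. The assumptions are explicit:

* **Homology → shared fold.** Hits are accepted at ≥ 25 % sequence identity
  over ≥ 85 aligned residues; below that, segment homology no longer implies
  structural similarity and nothing is transplanted.
* **Local rigidity.** Placement uses only the backbone atoms (N, CA, C, O)
  within 6 Å of the compound. Inter-domain motion between donor and model
  may inflate the *global* Cα r.m.s.d. arbitrarily without invalidating a
  transplant — the local fit, not the global one, carries the placement.
* **The model protein is immutable.** Transplants are added as new het
  chains; no model atom is ever moved or deleted. Consequently clashes are
  possible and are measured (TCS), not resolved. An optional post-processing
  hook on `fill` lets callers plug in an external refinement step, after
  which the TCS is recomputed.

## Pipeline parameters

| parameter | default | unit | role |
|---|---|---|---|
| `min_identity` | 0.25 | fraction | HSP identity cutoff (inclusive) |
| `min_hsp_length` | 85 | residues | aligned-length cutoff (inclusive, gap columns count) |
| `env_radius` | 6.0 | Å | donor backbone gathered around a compound |
| `dedup_radius` | 3.5 | Å | same-compound centroid deduplication (inclusive) |
| `contact_radius` | 4.0 | Å | minimum protein proximity for a placement (inclusive) |
| `clash_cutoff` | 4.0 | Å | TCS pair cutoff (strict `<`, per the definition) |
| `max_hits` | 250 | hits | search truncation before filtering |

Identity is counted over alignment columns including gaps (the convention
BLAST reports). The aligner is a gapped Smith–Waterman with BLOSUM62, gap
open 11 / extend 1; E-values use Karlin–Altschul gapped parameters
(λ = 0.267, K = 0.041, H = 0.14) with the standard edge-effect length
correction. Multiple HSPs per donor chain are found by masking the matched
donor segment and re-aligning; HSPs order ascending by E-value with ties
broken by identity, then (entry, chain) — this single ordering also decides
which donor wins a deduplication race, making runs deterministic.

## Scores

* **Global r.m.s.d.** — single-pass least squares over all HSP-matched Cα
  pairs; no iterative outlier trimming. Reflections are excluded in the
  Kabsch solution.
* **Local r.m.s.d.** — least squares over the 6 Å donor backbone mapped
  through the HSP correspondence plus identical atom name. Only the lowest
  altloc conformer of an environment atom contributes (determinism).
* **TCS** — r.m.s. van der Waals overlap over transplant–protein pairs at
  d < 4 Å. Overlaps are clamped at zero and non-overlapping pairs inside the
  cutoff still count in the denominator, a literal reading of "all distances
  shorter than 4 Å"; both choices are keyword-switchable in `scoring.tcs`
  for sensitivity analysis. The vdW radius table (Bondi main-group values,
  Batsanov/Alvarez-style metals) ships as `data/vdw_radii.tsv`; published
  tables disagree on metals, so absolute TCS values carry a table-choice
  caveat. Mono-atomic transplants get a TCS like any other but are tagged
  `mono_atomic` so population statistics can exclude them.
* **LEV** — the binding site is defined on the reference (ligand heavy atoms
  plus protein heavy atoms within 6 Å of them); pairs are found by residue
  number + atom name, the two sites are superposed on the paired *protein*
  atoms, and the score is the all-atom r.m.s.d. over protein and ligand
  pairs together. The superposition frame is a design choice — fitting on
  protein atoms only prevents a displaced ligand from dragging the frame
  toward itself. No symmetry correction is applied for ligands with
  flip-equivalent atom names.
* **Confidence** — high/medium/low per score from two cutoffs each, both
  comparisons inclusive. Shipped defaults (0.92 / 3.10 Å local r.m.s.d.,
  0.64 / 1.27 Å TCS) are Q3 + 1.5·IQR outlier bounds of large-scale
  transplant populations at ≥ 70 % donor identity and over all identities
  respectively; `derive_thresholds` recomputes the statistic (linear
  interpolation quantiles) on any population of ≥ 4 values.

## Synthetic fixtures: what they emulate and what they do not

`fixtures` generates the three inputs with known ground truth:

* **Models** are ideal α-helices (rise 1.5 Å, twist 100°/residue, Cα radius
  2.3 Å) with N, CA, C, O, CB at fixed local-frame offsets and a seeded
  random sequence. Glycine and proline are excluded from the alphabet —
  glycine so every residue carries a CB, proline because it has no
  non-identical BLOSUM62 partner scoring ≥ 0 (see below).
* **Donors** are derived at an *exactly* representable identity by point
  mutations only (no indels), spread evenly across the interior and chosen
  among substitutions with non-negative BLOSUM62 score. With every alignment
  column then scoring ≥ 0 and identical terminal residues, the optimal local
  alignment provably spans the full chain, so the reported identity equals
  the planted fraction exactly — this is what makes the end-to-end identity
  recovery test sharp. Isotropic Gaussian noise of σ per coordinate gives an
  expected pairwise r.m.s.d. of σ√3; tests accept the 0.6–1.1 band around it
  to absorb the fit's degrees of freedom. Ligands are planted radially off
  chosen pocket residues; an optional rigid motion of the second domain
  reproduces the inflated-global-r.m.s.d. scenario. The whole donor is
  finally moved into a random rigid frame so superposition is non-trivial.

The fixtures are geometric, not chemical: no rotamers, no real bond
topology, no crystallographic artifacts (alternate conformations and partial
occupancies are injected explicitly where tested). Passing tests therefore
demonstrate the *algorithmic* contracts — alignment, superposition, rule
boundaries, score arithmetic, determinism — not the biological quality of
transplants into real predicted models, which additionally depends on donor
curation and model accuracy.

## Numerical choices and degenerate inputs

* Kabsch uses SVD with the determinant sign correction; < 3 pairs or
  collinear point sets raise an alignment error (candidates are skipped, not
  fatal). R.m.s.d. values agree with an independent rotation-vector BFGS
  minimizer to < 1e-6 Å (acceptance check).
* All distance cutoffs are inclusive except the TCS pair cutoff, which is
  strict by its definition; inclusive comparisons carry a 1e-9 Å epsilon so
  boundary fixtures behave predictably in floating point.
* Centroids for deduplication average all non-hydrogen atoms across all
  conformers, unweighted by occupancy.
* Hydrogens are parsed and written but excluded from every geometric
  computation.
* Canonicalization never invents atoms: renames of absent atoms are logged
  and skipped, so analogs missing atoms relative to their parent transfer
  as-is.
* mmCIF coordinates are written at 3 decimals; round-trip tests tolerate
  1.5e-3 Å accordingly.

## Problem sizes

Tests and the acceptance script run on 120–200-residue fixtures with one or
two donors, 20-seed Monte-Carlo bands for noise recovery, 50 superposition
oracle instances, 25 clash-score configurations and 10⁴-sample threshold
checks — sizes at which every quantity the package computes is exercised
end-to-end in well under a minute each.

## Known limitations

* The aligner returns one optimal alignment per masking round; co-optimal
  alignments are not enumerated, so hit lists may differ from other search
  tools in ties.
* No structure-based remote-homology search: donors invisible to sequence
  search contribute nothing.
* Polymer ligands, glycans and post-translationally modified residues are
  out of scope; the registry deliberately excludes crystallization agents.
* Transplants are placed rigidly; resolving clashes requires an external
  refinement engine via the post-processing hook.
* The JSON metadata schema is this package's own; it is not byte-compatible
  with any external databank's format.
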