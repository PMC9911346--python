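# homofill

Predicted protein structures — AlphaFold-style models in particular — are
delivered apo: no cofactors, no metals, no substrates, even when the protein
is biologically inseparable from them (myoglobin without its heme, a zinc
finger without its zinc). `homofill` enriches such ligand-free models by
**transplanting** small molecules, cofactors and ions from homologous,
experimentally determined donor structures, and attaches per-transplant
quality scores so users can judge each placement.

## The algorithm

Given a query model, a local collection of donor mmCIF structures with their
per-chain sequences, and a CIF list of transferable compounds:

1. The model sequence is searched against the donor sequence database with a
   gapped local aligner (BLOSUM62, gap open 11 / extend 1); high-scoring
   segment pairs (HSPs) are ranked ascending by E-value (Karlin–Altschul
   statistics) and capped at 250 hits.
2. Hits are kept when sequence identity ≥ 25 % over an aligned HSP of
   ≥ 85 residues — enough to confer structural homology.
3. Each surviving HSP is superposed on the model over its matched Cα atoms
   (least-squares, Kabsch); the r.m.s.d. of this fit is the **global
   r.m.s.d.** of the hit.
4. For every transferable compound in the donor (analogs first mapped to
   their canonical parent, e.g. AGS → ATP, by atom renaming/deletion), all
   donor backbone atoms within 6 Å are superposed on their model
   counterparts; this **local r.m.s.d.** is the per-transplant fit, and its
   transform places the compound in the model frame.
5. A candidate is skipped when the same compound already sits within 3.5 Å
   of its centroid (deduplication across donors) or when no protein atom
   lies within 4.0 Å of it (no binding site). Multiple conformers and donor
   occupancies are carried over unchanged; donor `struct_conn` records
   (covalent and metal bonds) are re-addressed into the model.
6. Each placement receives a **transplant clash score**

   TCS = √( Σᵢ overlapᵢ² / N ),   overlapᵢ = max(0, rₐ + r_b − dᵢ),

   the r.m.s. van der Waals overlap over all transplant–protein atom pairs
   closer than 4 Å.
7. Local r.m.s.d. and TCS are mapped to high / medium / low confidence via
   Q3 + 1.5·IQR outlier cutoffs (shipped defaults 0.92 / 3.10 Å and
   0.64 / 1.27 Å); `derive_thresholds` recomputes them on any population.

The filled model is written as mmCIF next to a JSON metadata file recording
the provenance (donor entry/chain/copy, E-value, identity) and scores of
every transplant in placement order.

Against a sequence-identical experimental reference, the **LEV score**
(local environment validation) — the all-atom r.m.s.d. of the ligand plus
all protein atoms within 6 Å of it — provides independent validation
(`homofill validate`).

## Worked example

Synthetic fixtures make the pipeline fully reproducible without downloads: a
120-residue helical model, a donor at 70 % sequence identity with 0.3 Å
coordinate noise, a planted heme-like 8-atom ligand and a zinc ion.

```python
from homofill import (FixtureSpec, LigandSpec, make_model, make_donor,
                      make_registry, load_registry, fill)

spec = FixtureSpec(
    n_residues=120, target_identity=0.70, coord_noise_sigma=0.3,
    ligands=(LigandSpec("HEM", 8, tuple(range(40, 46))),
             LigandSpec("ZN", 1, (80, 81, 82))),
    seed=42,
)
model = make_model(spec)
donor = make_donor(model, spec)
registry = load_registry(make_registry(["HEM", "ZN", "ATP"], {}, "registry.cif"))

result = fill(model, [donor], registry)
for t in result.transplants:
    print(f"{t.comp_id:4s} from {t.donor_entry}/{t.donor_chain} copy {t.donor_copy}: "
          f"identity {t.identity_fraction:.2f}, global {t.global_rmsd:.2f} A, "
          f"local {t.local_rmsd:.2f} A, TCS {t.tcs:.2f} A "
          f"[{t.confidence_local}/{t.confidence_tcs}]")
```

prints

```
HEM  from donor42/A copy 1: identity 0.70, global 0.46 A, local 0.50 A, TCS 0.68 A [high/medium]
ZN   from donor42/A copy 1: identity 0.70, global 0.46 A, local 0.43 A, TCS 1.55 A [high/low]
```

The reported identity is exactly the planted 0.70 (point mutations, no
indels); global and local r.m.s.d. sit near the 0.3·√3 ≈ 0.52 Å expectation
for isotropic 0.3 Å noise; the zinc's higher clash score (its placement
presses into the synthetic pocket) demotes its TCS confidence, while both
placements are high-confidence by local fit.

The same run from a shell:

```
homofill fill model.cif donors/ registry.cif --out out/
homofill validate out/model42.cif out/model42.json reference.cif
homofill filter out/model42.json --cutoff 0.70
```

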