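# Methods

## Model and procedure

`classfx` operationalises drug class-effect detection as four statistics on
ingredient counts, computed per (drug class, AE term) pair.

**Counting unit.** The unit is the drug chemical ingredient, not the marketed
product. A product-level association table is collapsed first: ingredient *i*
is associated with AE *e* iff at least one product containing *i* reports
*e*; products with several ingredients contribute the AE to each. Product
dosage and dosage form are treated as opaque parts of the product identifier;
dosage-form effects on AEs are out of scope. The product level remains
available only for AE frequency ranking (`rank_top_aes`).

**Hierarchy semantics.** Drug classes and AE terms live in rooted DAGs of
is-a edges (multi-parent terms allowed). A drug class is always resolved to
its member set at call time — the intersection of the class node's downward
closure with the ingredient universe — and class memberships may overlap
freely. AE associations are closed upward: an ingredient with diarrhea is
also associated with every more general AE class above it, along *all*
parent paths (union semantics). Propagation adds ancestors strictly below
the global AE root: against the root every drug with any AE has PCR = 1,
which carries no information. Propagation is idempotent and never removes
an association.

**Statistics.** For class member set *C* and AE-positive set *P* within the
background universe *U*:

* PCR = |C ∩ P| / |C| ∈ [0, 1]; PCR = 1 ⇔ the contingency cell c = 0.
* Contingency cells: a = |C ∩ P|, b = |P \ C|, c = |C \ P|,
  d = |U| − a − b − c.
* C-PRR = (a/(a+c)) / (b/(b+d)). By convention: 0 when a = 0; +∞ when
  b = 0 with a > 0. The infinite case *passes* the C-PRR cutoff — the
  disproportionality is maximal — but results carry a `zero_background`
  flag so consumers see the degeneracy.
* χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)), the 2×2 Pearson closed form;
  with the Yates option, |ad − bc| is shrunk by N/2 (floored at 0). A table
  with any zero marginal returns 0 (no information).

**The background universe** for b and d is the set of ingredients mapped
into the classification scheme under analysis — not every drug in the raw
table — because ingredient-class and MoA-class schemes typically cover
different subsets of the data. It defaults to the leaf terms of the class
hierarchy (minus its roots and the scored class ids themselves, since a
childless class node is not an ingredient) and can be pinned explicitly.
Ingredients in the scheme but absent from the table count as AE-free
background.

**Significance filter.** A pair is significant iff PCR = 1 ∧ C-PRR ≥ 2 ∧
χ² > 4 ∧ class size ≥ 3. Defaults follow the customary signal-detection
cutoffs (PRR ≥ 2; χ² > 4, roughly p < 0.05; a minimum-count filter
transplanted from minimal case reporting to minimal ingredients per class).
Each pair is scored independently; no multiplicity adjustment is applied
beyond the three-criterion rule, but every result row carries the number of
pairs tested so users can apply their own.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `c_prr_min` | 2.0 | C-PRR cutoff (dimensionless ratio) |
| `chi2_min` | 4.0 | χ² cutoff (≈ p < 0.05 at 1 df) |
| `min_ingredients` | 3 | minimum class size counted in ingredients |
| `yates` | off | continuity correction for χ² |
| clustering `metric` / `linkage` | euclidean / average | heatmap ordering |

χ² defaults to the uncorrected Pearson statistic; published class-effect
tables do not always state the variant, so both settings are exposed and the
detection report records which was used.

## Heatmap

The PCR matrix holds one PCR per (drug class, AE class) cell, with AE class
membership resolved through propagation; classes with no mapped ingredient
are dropped with a warning. Row and column orders come from agglomerative
clustering (scipy linkage), with one refinement: at every dendrogram merge
the two subtrees are emitted in lexicographic order of their smallest member
row, so the ordering is a pure function of the cell values — permuting the
input rows cannot change the clustered sequence. The matrix TSV round-trips
bit-exactly (17-significant-digit floats); the rendered image is a
convenience and never alters cell values. The AE-class level for columns is
always given explicitly by the caller; no level is inferred from the
hierarchy.

## Synthetic studies

The generator emulates the statistical shape of a curated package-insert
master table. Defaults: 194 ingredients in 36 classes (sizes 5–6, covering
the universe, optional overlap), 736 leaf AEs in a depth-3 hierarchy
(intermediate level sizes interpolate geometrically; parents round-robin),
1–3 products per ingredient, background ingredient–AE association
probability `p_bg` = 0.04 — about 30 AEs per ingredient, the order of
magnitude of a package insert's adverse-reactions list. Background
associations are drawn at the ingredient level and attached to one randomly
chosen product, matching the direction of the collapse rule; planted class
effects are placed at leaf AEs so detection at ancestor AE classes exercises
propagation. Generated products carry a single ingredient; multi-ingredient
fan-out is covered by unit tests of the collapse operation itself.

What the generator does **not** model: AE co-reporting correlation
(real AEs co-occur in syndromes), heterogeneous class sizes and heavy-tailed
AE frequencies, translation noise between term languages, and
partially-mapped ontology ids. Passing tests on synthetic data therefore
demonstrate correctness of the counting, propagation and filtering
machinery and the filter's operating characteristics under independence —
not calibration on real reporting data.

`estimate_operating_characteristics` replays the full detection pipeline
over seeded replicates (per-replicate seeds derived linearly from the base
seed, kept below 2³¹) and reports planted-pair recovery and per-pair
false-positive rates with binomial standard errors.

## Numerical choices and degenerate inputs

* All counts are exact integers; PCR and C-PRR are exact ratios of small
  integers reported as doubles.
* Empty class → PCR undefined (error); scoring drops empty classes with a
  warning instead of failing a whole run.
* b + d = 0 (class spans the whole universe) → C-PRR undefined; the
  detection result records NaN, which fails the C-PRR criterion.
* AE records without an ontology id are retained for product/term counting
  but excluded from hierarchy-propagated analyses; their count is logged.
* Ranking ties break lexicographically on the AE identifier; result rows
  sort by (class id, AE id); all orderings are deterministic.

## Scale of the shipped checks

The test suite and acceptance script run entirely on generated data: the
noiseless recovery check uses 100 replicates of 20 ingredients × 10 leaf
AEs; the noisy cross-check against a brute-force oracle uses 25 replicates
of 80 ingredients × 30 leaf AEs at `p_bg` = 0.3; the acceptance script runs
the master-file-scale configuration (194 × 736, five planted effects) once
plus five Monte-Carlo replicates. These sizes were chosen as the smallest
that exercise every code path with non-trivial backgrounds.

## Known limitations

* The three-criterion filter controls no family-wise error rate; with
  thousands of pairs, users should treat the emitted `n_pairs_tested`
  column as an invitation to adjust.
* C-PRR's infinity convention makes zero-background effects pass the
  cutoff by design; filter on the `zero_background` flag to exclude them.
* Bayesian shrinkage alternatives (BCPNN, GPS) and odds-ratio variants
  (ROR, Fisher exact) are deliberately out of scope.
* Spreadsheet master files must be converted to the canonical TSV dialect
  before analysis; the statistics path reads only the documented dialects.
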