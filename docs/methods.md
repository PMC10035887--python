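# Methods

## Site classes and annotation transfer

Every analysis is anchored on the human sequence of each orthogroup.
Binding profiles assign, per (domain, ligand type) pair and per match
state, a binding frequency *f* ∈ [0,1] — the fraction of co-complex
structures in which that domain position contacts the ligand — and one
cross-validation precision *p* ∈ [0,1] per pair. Classification is
threshold-based: *binding* iff *f* ≥ 0.10 and *p* ≥ 0.50 (0.75 for
ions, whose coordination geometry produces more spurious contacts);
*non-binding* iff *f* = 0; anything else *excluded*. Both thresholds
are inclusive and configurable in `PipelineConfig`.

Labels travel through domain matches (match state → 1-based human
position) onto MSA columns. Where overlapping matches disagree, the
precedence is binding > excluded > non-binding: a position observed in
contact with any ligand in any structure is a binding site. This
tie-break is our choice; the alternative (excluded wins) removes a
small number of multi-domain positions and does not change any class
comparison qualitatively. The five column classes —
`ligand_binding`, `other_within_domain`, `other_outside_domain`,
`excluded`, `unannotated` (human-gap columns) — partition the columns,
and the first four partition exactly the human residues. "Other sites"
pools the two non-binding classes; "other sites within domains" is the
preferred background because domains are themselves constrained.

## Orthogroup quality control

Each non-human sequence is globally aligned to the human sequence with
Needleman–Wunsch under BLOSUM62, gap open 10, gap extension 0.5, free
end gaps (the EMBOSS Needle defaults). Similarity counts identical
pairs plus positive-scoring (biochemically conservative) pairs over the
full alignment length including gap columns; the gap percentage uses
the same denominator. A species is removed when similarity < 80% OR
gaps > 10% (both thresholds read disjunctively and inclusively on the
keep side), or when it fails the match-state register check.

The register check is a declared reconstruction: a species fails iff it
has a gap at an alignment column carrying a human domain match-state
residue while having non-gap residues both before and after that column
in its row. This catches internal deletions and alignment shifts that
break match-state homology while tolerating terminal truncations and
gaps outside domain spans. Orthogroups keep ≥ 10 retained sequences
(human always retained — it cannot fail a self-comparison) or are
rejected.

## Per-site conservation metrics

**Entropy.** H = −Σₐ qₐ ln qₐ over amino-acid frequencies among
non-gap residues (natural log; no window, no gap penalty). All-gap
columns are missing. H = 0 iff the column is conserved (exactly one
distinct non-gap residue), which is also the variability
classification.

**ML rate.** Per column, the likelihood is the Felsenstein pruning
recursion on the fixed rooted species tree with transition matrices
P(r·t) = exp(Q·r·t); the root is weighted by the stationary
distribution π. Q is an empirical amino-acid model — JTT by default,
WAG and LG available — normalised to one expected substitution per
unit time, so branch lengths and r share units. Gapped leaves get
all-ones partial likelihoods; because transition-matrix rows sum to
one this is exactly equivalent to pruning those leaves from the tree,
so the tree is never rebuilt per column.

r̂ maximises the likelihood over [1e-6, 20]: a 17-point log-spaced grid
(evaluated for all columns of an orthogroup simultaneously) followed by
bounded scalar minimisation (tolerance 1e-6) around *every* local
maximum of the grid, keeping the best. Refining all grid modes matters:
a minority of columns have bimodal likelihoods in r and a single-mode
refinement can lock onto the wrong peak. Invariant columns are pinned
to the lower bound (their likelihood is decreasing in r). These are ML
point estimates, not empirical-Bayes posterior means.

Raw rates are not comparable across orthogroups, so per-orthogroup
vectors are rescaled to mean one before pooling ("normalized_rate");
both raw and normalised values are emitted. An all-invariant orthogroup
carries no rate information and is set to ones with a warning.

## Statistical battery

* Fisher's exact test (two-sided, point-probability convention) on
  conserved/variable 2×2 tables, computed in log space via log-gamma so
  genome-scale counts (~10⁶) do not overflow. Zero-margin tables return
  p = 1 with a warning.
* Mann–Whitney U on pooled rates/entropies: exact enumeration when both
  samples have ≤ 20 observations (and no ties), otherwise the
  tie-corrected normal approximation with continuity correction.
* Kruskal–Wallis (tie-corrected) across the five ligand-type groups; a
  site bound to several ligand types joins each of its groups, matching
  the per-ligand accounting of the conservation table.
* Conover–Iman all-pairs post-hoc on pooled ranks, t distribution with
  N−k df, Bonferroni over the 10 pairs, direction from mean ranks.
  Implemented in-repo (no suitable dependency available) and
  cross-checked in the tests against an independently coded reference.

## Lineage-specific scans and population filter

Strict mode requires all focal taxa to share residue X and all
non-focal retained taxa to share a different residue Y; relaxed mode
drops the background-fixation requirement but forbids X anywhere in the
background. Columns with any gap among retained species are ineligible
— fixation cannot be asserted across missing data. Candidates pass the
population filter iff every variant at their (gene, human position) has
allele frequency ≤ 0.01 (inclusive) and no disease flag; matching is by
site, not allele, and disease-flagged rare variants do disqualify (the
conservative reading; configurable via the variant table).

## Enrichment

Per protein, fold enrichment
F = (variable binding / binding) ÷ (variable other-in-domain /
other-in-domain); F = ∞ when the background has no variable sites but
the interface does (sorted above all finite values); a protein
qualifies when F ≥ 2 and it has ≥ 2 variable binding sites. The
variable-interface gene set keeps a gene as long as *any one* of its
variable binding sites is free of common (AF > 0.01) variation — the
filter is per site, not per gene. GO over-representation is a one-sided
hypergeometric upper tail per term against the ligand-binding
background with Benjamini–Hochberg FDR; annotation tables are assumed
ancestor-propagated (no ontology-graph handling).

## Synthetic data: what it emulates and what it does not

The generator produces the full input set with known ground truth.
Sequences evolve site-independently down the packaged tree under the
same empirical model family used for inference (a mismatched-model mode
exists for robustness checks); per-site rates are gamma(shape, mean 1)
draws multiplied by `rate_multiplier_binding` (default 0.5) at binding
columns. Simulation is indel-free — columns align by construction, so
alignment inference never confounds parameter recovery; the QC gates
are instead exercised with perturbed fixtures in the tests. Planted
human-specific substitutions overwrite the human residue with an amino
acid absent from the column, at binding columns monomorphic across the
other species (the strict scanner's definition); planted sites receive
only rare, non-disease variants. One GO term can be planted on a chosen
gene set to give the enrichment stage a true positive.

The default binding annotation density (≈ 50% of the sequence covered
by domains, ≈ 20% of covered match states above the frequency cutoff)
yields roughly 10–12% of columns as binding sites, comparable to real
domain-centred datasets. What the simulation does *not* reproduce:
indels and alignment error, site-to-site rate autocorrelation,
among-branch rate variation, correlated substitution processes at
interacting positions, and realistic gene-family structure in the GO
table. Passing recovery tests therefore demonstrates correctness of
the estimators and scanners under the model, not robustness to every
property of real proteomes.

## Reference tree

The packaged tree (`ligevo/data/primate18_synthetic.nwk`) is synthetic:
an 18-taxon primate-like topology (six apes, eight monkeys, four
prosimian-grade taxa) with hand-set, plausible relative branch lengths
scaled to a total length of ~1.0 expected amino-acid substitutions per
site — a moderately evolving protein. This depth keeps roughly half of
simulated columns fully conserved while leaving enough substitutions
for per-column rate estimation to be informative. Under the QC gates
the most divergent taxa occasionally drop below the 80% similarity
threshold, so retained orthogroup sizes concentrate just below 18, as
in real primate ortholog sets. Clade sets `human`, `great_apes`
(human, both chimpanzees, gorilla, orangutan) and `apes` are attached
for the scanners.

## Validation experiments and problem sizes

`ligevo.experiments` runs three studies under the generator's default
conditions, pooling orthogroups (350 residues each) until each site
class reaches the required count:

* **Rate recovery** (multiplier 0.5, ≥ 200 sites per class, 50 seeds in
  the tests): the fraction of seeds with binding rates significantly
  below other rates (two-sided MWU, p < 0.01, correct direction) and
  the Spearman correlation between true and estimated rates. About
  half of all columns are invariant at this tree depth and tie at the
  rate lower bound, which bounds the achievable rank correlation; the
  pooled mean Spearman lands just above 0.6.
* **Null calibration** (multiplier 1.0, 200 replicates in the tests):
  empirical type-I error of the Fisher and MWU comparisons at α = 0.05,
  checked against the 3σ binomial band.
* **Planted-site recovery**: strict-scanner sensitivity on planted
  human-specific binding sites (must be 1.0), plus a spiked common
  variant that must disqualify its site.

`scripts/acceptance.py` reruns these at 30 seeds / 120 replicates —
sizes chosen to keep a single-CPU run in the minutes range while
leaving the binomial bands meaningful — alongside the reference-count
statistics and the brute-force oracles.

## Known limitations

* Rates are per-column point estimates on a fixed tree; no
  rate-smoothing prior, no branch-length re-estimation, no among-site
  rate model is fitted jointly.
* The match-state register check is a reconstruction of an informally
  specified filter; alternatives (e.g. requiring exact column
  correspondence per match state) would be stricter.
* The Fisher/MWU battery treats columns as independent observations;
  within-protein correlation is ignored, as in the standard pooled
  analyses this package mirrors.
* GO enrichment assumes pre-propagated annotations and tests terms
  independently.
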