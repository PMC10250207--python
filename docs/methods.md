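# Methods

## The strategy in one paragraph

Clonal lines derived from the same local clonal expansion are redundant:
they inherit essentially the same mosaic mutation set from their shared
founder cell. Shallow (5×) sequencing detects roughly half of a founder's
mutations per line — enough to recognize redundancy — after which the
shallow data of each redundant cluster are summed into one effective
≥15× genome per lineage. Only lines that share mutations with nobody
("unique" lineages) need individual high coverage. Mutations are then
re-discovered across the merged clusters and unique lines by exhaustive
pairwise comparison, scored for consistency with a carrier/non-carrier
bipartition, and the carrier sets of the surviving mosaic variants are
arranged into a lineage tree.

## Pairwise caller contract

`counts_calls.call_pair(case, control, params)` emits a variant iff

* case alt reads ≥ `min_alt_reads` (default **3**),
* control alt reads ≤ `max_control_alt` (default **0**),
* control depth ≥ `min_control_depth` (default **6**),
* the site is inside the accessibility mask (if one is supplied).

This single explicit rule stands in for a consensus of two production
somatic callers; its virtue is reproducibility. The control-depth floor
prevents germline alleles from leaking through control dropout, which at
5× is common. Post-call filters: VAF ≥ `min_vaf_postfilter` (default
**0.30**, removing culture-acquired mutations whose VAF is well below the
clonal 50%) and indel length ≤ **9 bp**. A 0.20 VAF cut admits calls that
conflict with tree branches; 0.40 starts deleting genuinely shared
mutations — both remain available in `CallerParams`. In the pairwise
table the VAF/indel filter is applied per pairwise call
(`apply_postfilter=True`), i.e. a sub-threshold call does not count as
evidence of carriage.

## Clustering

Distance between two lines is `1 − J` over their call-site sets, where a
site is the full (chrom, pos, ref, alt) tuple. Two empty call sets get
distance 1 — absence of evidence is not redundancy. Agglomeration is
Ward's minimum-variance method in the D2 variant (squared distances in
the Lance–Williams update); the loop is written out so that equal-height
merges resolve deterministically (lowest node-index pair first) instead
of depending on library internals; scipy's implementation serves as an
independent oracle in the tests. The default cut accepts the largest
dendrogram nodes whose every within-pair similarity is J ≥ `s_min`
(default **0.10**); a line whose best similarity to anyone is below
`j_max` (default **0.02**) is pooled into the 'Unique' cluster. Both
defaults were calibrated on the simulator, since with independent ~50%
detection two redundant lines share about J ≈ 1/3 of their detected
sites while unrelated lineages share almost nothing after bulk-relative
calling.

## Clonality QC

For each line, count detected mutations with measured VAF strictly above
and strictly below 50% (exact ties excluded; the VAF postfilter must NOT
have been applied). Ratio > 3 → clonal, < 2 → nonclonal, 2–3 →
inconclusive. The discriminative power comes from detection bias: at 5×
a true-VAF-0.5 mutation is mostly detected when the binomial draw lands
high, while a mixture line's 25%-VAF mutations are detected rarely and
measured low more often. The pipeline excludes every line not positively
classified clonal (nonclonal, inconclusive or no-data): downstream units
must be confirmed clonal samples. This is deliberately stricter than
dropping only certain nonclonal lines — an unconfirmed two-founder line
promoted to a high-coverage unit injects mixed carrier patterns that
corrupt two lineages at once.

## Mosaic/germline scoring

For each variant in the pairwise call table, A is the set of units
called as case in at least one ordered pair, B the complement.

* `M = #called pairs (i∈A, j∈B) / (|A|·|B|)`, 0 when either side is
  empty. A variant carried by *every* unit has B = ∅ and M = 0, so it is
  decided purely by G — germline-like by construction.
* `G = #called pairs whose control unit has ≥1 supporting read / #called
  pairs`.

Classification: germline iff `G > 0.2`; else mosaic iff `M ≥ 0.8`;
mosaic variants carried by ≥ 75% of units are flagged high-frequency
mosaic (early-development mutations that resemble germline variants and
are missed by bulk-referenced calling); everything else is a false
positive. These score definitions are this package's own concrete
reconstruction of pattern-based pairwise filtering — unweighted (pairs
are not weighted by coverage), with thresholds exposed and calibrated on
the simulator.

## Tree construction

Variants with identical carrier sets merge into branch groups. A set of
groups is realizable as a tree iff carrier sets are pairwise nested or
disjoint (a laminar family); violations form a conflict graph whose
vertices are groups. The removal set is an exact minimum-weight vertex
cover with weight = number of member variants (branch credibility grows
with independent mutation support), ties broken towards fewer groups,
then fewer variants / smaller carrier set / lexicographic order; beyond
20 conflicted groups an equivalent greedy (drop the cheapest conflicted
group first) takes over. Removed groups are reported, not discarded
silently. The root always carries all units (the zygote is implicit);
sibling order is meaningless and unresolved branching is emitted as
multifurcations. Trees are compared by their non-trivial internal clades
(recovered fraction, precision, Robinson–Foulds distance).

## Mitochondrial track

Heteroplasmy fractions drift across divisions and variants can disappear
entirely, so presence/absence is unusable; lines are instead clustered
on VAF vectors. Per site, a Pearson χ² test of ref/alt independence
across samples (no continuity correction, BH-corrected across sites,
retain q < 0.05) removes homogeneous low-frequency artifacts. Distances
are `1 − ρ` (Pearson correlation over sites observed in both samples,
pairwise deletion; range [0, 2] kept literally; ρ undefined → distance 1,
flagged). Ward agglomeration and cutting reuse the nuclear machinery.

## Sequencing plan and cost

`sum_all` merges every non-Unique multi-line cluster; `pick_one` merges
clusters of > 3 lines and represents 2–3-line clusters by one
high-coverage line (existing if available, else one member is queued for
new sequencing; optionally such clusters are skipped). Unique lines are
sequenced to 15–30×. Cost: baseline `n_lines × price_high` versus
`n_lines × price_shallow + n_unique_high × price_high` with defaults
$600 per 30× and $150 per 5× genome. Both the exact saving and a
nearest-$1000 rounding are reported: the canonical 72-line / 10-unique
example gives $26 400 exactly, ~$26 000 rounded.

## The simulator

* **Lineage**: a synchronous binary tree of `n_divisions_tracked`
  (default 6) tracked divisions; each daughter gains
  Poisson(`muts_per_division`, default 200) mutations at unused sites,
  so a founder carries ~1200 mosaic mutations — the observed 1000–2000
  per clone — and root-to-leaf edge sets are disjoint by construction.
  A tracked "division" is a coarse-grained epoch, not a literal cell
  cycle.
* **Sampling**: each of `n_biopsies` (4) biopsies takes
  `clones_per_biopsy` (11) lines in clonal expansions of
  1 + Poisson(`redundancy` − 1) lines per founder leaf (founders drawn
  without replacement; `biopsy_bias` can skew sampling towards one side
  of the first division to emulate lineage dominance). Two nonclonal
  two-founder mixture lines (mix ~ U(0.3, 0.7)) are added by default.
* **Sequencing**: per site depth ~ Poisson(coverage) (optional
  Gamma–Poisson overdispersion), alt ~ Binomial(depth, true VAF);
  detection at ≥ 3 alt reads. At 5× and VAF 0.5 the compound sum gives
  ~0.47 sensitivity — "roughly half". Culture mutations are line-private
  with true VAF ~ U(0.05, 0.3), i.e. below the 30% postfilter by
  construction. Germline heterozygous sites (40) are present in every
  line and in bulk at VAF 0.5.
* **Bulk**: internal-edge mutations appear in bulk at VAF 0.5 × (fraction
  of tracked leaves below the edge) — early mutations are partially
  suppressed in per-line bulk-referenced calling, which is exactly why
  the pairwise rescoring of merged units is needed. Terminal-edge
  mutations are absent from bulk: a tracked leaf coarse-grains one
  clone-founder lineage whose late mutations occupy a negligible body
  fraction.
* **Mitochondria**: `mito_sites` (30) heteroplasmy fractions start at
  U(0.05, 0.6) in the root and take clipped Gaussian steps
  (sd `mito_drift_sd` = 0.03) down every edge, plus one per-line culture
  step; 0 (loss) and 1 (fixation) are absorbing. Read counts are drawn
  at ~1000× effective coverage.
* **Determinism**: every draw uses an RNG keyed by (seed, stage, entity
  id), so adding a line never perturbs existing lines and a fixed seed
  reproduces the truth byte-for-byte.

What the simulator does **not** model: read-level errors and artifacts,
mappability structure, mutational signatures, CNVs/LOH, index swaps,
overdispersed clone mixtures beyond two founders. Passing tests therefore
demonstrate the *logic* of the strategy under idealized counts, not
robustness to platform noise; on real data the caller-consensus and mask
stages absorb part of that risk.

## Problem sizes and numerical choices

Simulation-backed checks run at desk scale, chosen as the package's
validation conditions: ~45 lines (12–15 redundant groups) per replicate,
20 seeded replicates for the end-to-end edge-recovery and
nuclear-vs-mito comparisons; 12 groups × 45 lines × 4 burdens × 20
replicates for the clustering-burden experiment; 50 lines × 2000 sites
for the clonality-ratio experiments. Jaccard/Ward/score computations are
exact; the only tolerances are Monte-Carlo (3–4 SE bands in tests).
Degenerate inputs are defined, not special-cased: empty∪empty call sets
get distance 1, χ² on collapsed tables returns p = 1 with a flag,
undefined Pearson correlations become distance 1 with a flag, a variant
carried everywhere gets M = 0, and the clonality ratio uses +inf / None
sentinels rather than caps.

## Known limitations

* The pairwise caller is a deliberately simple contract; it does not
  emulate caller-specific error models, and ingesting externally called
  VCFs (allele-exact PASS records with AD/DP) is the supported path for
  real data.
* Cluster cutting (`s_min`) and uniqueness (`j_max`) defaults are
  simulator-calibrated; very uneven real-world burdens (the low-burden
  borderline-cluster situation) may need adjustment, and instability
  under burden downsampling is reported rather than resolved.
* The mosaic/germline score formulas are a reconstruction, not a port of
  any existing tool's internals; pair weighting by coverage is knowingly
  omitted.
* `run_pipeline` on a sample sheet reuses existing counts for units the
  plan would send for new sequencing (with a warning) — it cannot
  conjure unperformed experiments.
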