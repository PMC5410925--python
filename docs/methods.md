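# Methods

`phylograft` builds large time-calibrated species-level phylogenies by a
divide-and-graft strategy and ships the simulation machinery to validate the
whole procedure against a known generating tree. This note describes the
models and algorithms as implemented, the defaults and why they were chosen,
and what the synthetic tests do and do not establish.

## The divide-and-graft procedure

1. **Data reduction and merging.** Homology clusters (single-linkage groups of
   sequences around a seed) are trimmed to `per_species_keep` sequences per
   species (default 1), ranked by fewest IUPAC ambiguity symbols, then by
   gap-free length closest to the species' median length in that cluster, then
   by seq_id. The ambiguity-first order is a fixed convention; the two
   criteria are equally defensible in either order and ties are rare in
   practice. Sister clusters of one marker are detected by comparing *seed*
   sequences all-versus-all with k-mer Jaccard similarity (k = 8, threshold
   0.5 — calibration choices of this package; an external BLAST-like tool can
   be slotted in) and merged by single linkage, then reconciled by profile
   alignment: global dynamic programming over column frequency profiles with
   expected sum-of-pairs scoring (match +1, mismatch −1, gap −2, terminal
   gaps free). Traceback ties align a column pair only when its expected
   score is positive; otherwise a gap column is inserted, keeping
   disagreeing columns unaligned.

2. **Exemplar selection.** Species sharing too few markers are removed first:
   a species must co-occur with a congener in ≥ `min_shared_intra` alignments
   (monotypic genera exempt) and with a non-congener in ≥ `min_shared_inter`
   alignments (defaults 1/1; the filter is named in the literature without
   numbers, so the thresholds are explicit configuration here). For each genus
   and alignment holding k ≥ 2 congeners, all pairwise distances are computed
   (JC69 with pairwise deletion by default; p-distance available) and the most
   distal pair gets a vote of weight n − 1, n = k(k−1)/2 within-genus
   comparisons — a distal pair found among many comparisons is more likely to
   span the genus root. The pair with the highest accumulated weight becomes
   the exemplars; every tie breaks lexicographically by species_id, making the
   result independent of input order. The `n` counted here is the number of
   within-genus comparisons (not alignment-wide); with per-alignment voting
   this is the reading consistent with distances being computed "within the
   genus".

3. **Supermatrix assembly (greedy knapsack).** Candidate alignments must pass
   a saturation filter (mean finite pairwise distance ≤ `max_avg_divergence`,
   default 0.25; saturated pairs are excluded from the mean and reported).
   Species are visited in ascending participation, and for the focal species
   its alignments are added in descending taxon coverage until the focal
   species holds `max_markers_per_species` selected markers. The maximum is a
   stopping rule for the focal species only; other species may exceed it
   through shared alignments. Species ending below `min_markers_per_species`
   are dropped afterwards in a single pass (no reselection), and any selected
   alignment emptied by those drops is removed too. Marker-graph density and
   mean shortest-path length (largest component) are reported as diagnostics;
   graph modularity is out of scope.

4. **Backbone inference and dating (built-in stand-ins).** The built-in
   inference is neighbor joining on JC69 distances with per-partition
   column-resampling bootstrap; support is the fraction of replicate trees
   containing each original split. Taxon pairs with zero comparable sites
   (possible in sparse supermatrices) get the three-point/ultrametric
   fill-in `min_k max(d_ik, d_jk)` in `impute` mode — the distance
   counterpart of how likelihood engines tolerate non-overlapping taxa. The
   built-in dating (`mpl-scale`) ultrametricises by mean path length (each
   node's relative age is the mean node-to-tip path length, clamped so a
   parent is never younger than its children) and applies one global factor
   `f = max_i(min_age_i / relative_age_i)` over the fossil placements, so all
   minimum ages hold and one holds exactly; maximum ages are verified after
   scaling. These are explicitly *not* reimplementations of ML/Bayesian
   inference or penalized-likelihood smoothing — production runs use external
   engines through the adapter contract (a command template producing Newick),
   and the stand-ins exist so the full pipeline runs and is testable offline.
   Rooting uses a configured outgroup when given, else midpoint. When several
   backbone trees are supplied, each is dated independently and per-clade age
   2.5/97.5% quantiles become the HPD annotations.

5. **Decomposition and grafting.** A genus is monophyletic when the MRCA of
   its exemplar tips subtends only tips of that genus. Non-monophyletic
   genera are merged with every genus having exemplars under the smallest
   backbone clade containing the offender's exemplars, iterated to a fixed
   point with union-find, so each task's exemplar MRCA subtends exactly the
   task's tips. A merged task is anchored at the dated-backbone age of the
   MRCA of *all* its exemplars (the natural generalisation when per-genus
   calibration nodes disappear by merging). Each clade tree (built-in: NJ on
   mean per-alignment distances, midpoint-rooted, MPL-ultrametricised, root at
   relative age 1) is rescaled by `f = calibration_age / relative_age(exemplar
   MRCA)` — ages and HPD bounds alike — and the exemplar MRCA is pinned to
   the backbone age exactly (bit-for-bit, as stored node ages rather than
   recomputed sums). If the exemplars span the clade root, the backbone clade
   is replaced outright; otherwise the overshoot `d = root_age − mrca_age` is
   subtracted from the stem. `d ≥ stem` would create a negative branch: the
   default is a hard error naming the clade, and `clamp` mode instead
   re-rescales the subtree to sit just below the backbone parent with a loud
   diagnostic (the anchor age is sacrificed). Grafts apply in descending
   backbone-age order; fossil-derived minima and ultrametricity are
   re-validated on the final tree.

## Replication machinery

`fit_birth_death` maximises the classical constant-rates birth–death
likelihood of the branching times, conditioned on the number of tips, over
(net diversification r, turnover ε) with bounded L-BFGS-B from several
starts (ε ∈ [0, 1−10⁻⁶]). `simulate_bd_tree` runs the process forward from
two crown lineages and stops at a uniform point of the waiting interval after
the extant count first reaches n; full extinction rejects and restarts, and
extinct lineages are pruned. Under this stopping rule a Yule cherry (n = 2)
has root age U·Exp(2λ), mean 1/(4λ) — the closed form the Monte-Carlo test
checks. The rule is a simple-sampling convention; it carries the usual mild
bias relative to age-conditioned samplers, which is acceptable here because
the replicate's purpose is structural realism, not exact age distributions.

Genus assignment walks the reference genus profile in descending size and
gives each genus the unused clade with tip count closest to the target
(ties: crown age closest, then seeded random; candidate clades are capped at
twice the target size so small genera never swallow deep clades). Leftover
tips become monotypic genera. The matching objective is this package's own —
the upstream description asks only for an approximate size/age distribution —
and deviations are reported, not hidden.

Substitution models {JC69, K2P, HKY85, GTR} × {+Γ₄, homogeneous} are scored
by maximum log-likelihood (Felsenstein pruning over site-pattern-compressed
data, 4-category discrete gamma with mean-of-interval rates) on a fixed NJ
guide topology; AIC picks the winner and ties go to the simpler model. Branch
lengths come from the NJ tree and a single global rate-scale factor is
optimised jointly with the substitution parameters — full per-branch ML
optimisation across eight candidate models is deliberately out of budget for
an offline stand-in. This preserves likelihood nesting (GTR ≥ JC69) and model
recovery, but absolute likelihoods are below the per-branch optimum, so AIC
differences between near-equivalent models are less sharp than a full ML
treatment would give. Sequence simulation evolves a root draw from the
stationary frequencies along the chronogram via the eigendecomposition of the
reversible rate matrix, at `rate` substitutions/site/Ma; per-site discrete
gamma categories apply when α is set. The optional indel overlay (default
off, as nothing states its parameters) is deletion-only: Poisson events per
branch with geometric span lengths, gaps shared by descendant lineages.

`replicate_dataset` chains these stages: fit the birth–death model to the
reference tree, simulate a same-sized tree, assign genera from the reference
profile, map reference species to simulated tips genus-preservingly, fit a
substitution model per reference cluster, estimate the cluster's clock rate
as mean divergence over mean pairwise time separation, simulate on the mapped
occupancy row, and drop invariable alignments (reported in the summary). The
occupancy of the replicate equals the reference occupancy under the mapping
by construction.

## The stated validation world

The fixture generator defaults encode the end-to-end test: 40 species in 8
genera (sizes 10/8/6/5/4/3/2/2), birth 0.3 and death 0.1 per lineage per Ma,
6 clusters of 1500 sites under HKY85+Γ (κ = 4, α = 0.5, base frequencies
0.3/0.2/0.2/0.3 — a mildly AT-rich composition typical of organellar
markers), a clock rate of 0.005 substitutions/site/Ma, and independent 75%
per-species cluster occupancy with every species guaranteed at least one
cluster. Fossil minima for dating come from the simulated truth: the root
and the two oldest nodes at which whole genera diverge, naming all descendant
species so the constraint keeps its node identity under exemplar subsampling
(how real fossil tables calibrate genus/family-level splits). The end-to-end
run uses graft clamp mode, decided before any measurement: a hard error would
void a whole replicate whenever an inferred clade root overshoots its stem,
an event the source framework observed empirically.

What a green end-to-end test establishes: the assembled pipeline recovers
topology (mean normalized RF ≤ 0.15) and root age (within 15%) from clean,
clock-like, indel-free data at moderate divergence with correct fossil
minima. What it does not establish: robustness to alignment error,
among-lineage rate variation, model misspecification, incomplete lineage
sorting, or fossil misplacement — none of which the generator emulates.

## Distances and binning

Robinson–Foulds uses non-trivial unrooted splits and is normalized by the
*sum* of both trees' split counts, so maximally different binary trees score
1.0. The squared branch-length (Kuhner–Felsenstein) distance sums squared
differences over the union of bipartitions, terminal branches included,
absent bipartitions contributing length 0; its normalization divides by the
union size by default, with the sum convention available behind a switch
(the literature sentence covering both normalizations does not disambiguate).

Dispersal events are range gains along branches of an area-annotated
chronogram: each gained area yields one event per source area in the parent
range, weighted 1/|parent range| so a gain totals one event (a flag switches
to one full event per source). Events are smeared over time bins (default
5 Ma, anchored at 0, closed on the older edge) in proportion to branch–bin
overlap; the relative series divides by the total branch length per bin
(0/0 → 0). Exact conservation — bin contributions summing to the event
weight, bin branch lengths summing to tree length — is enforced to 1e-12.

## Numerical conventions

- Ages run backwards from the present (extant tips at 0 Ma); dated branch
  lengths are age differences, and node ages are stored as primary data so
  calibrated ages survive grafting bit-for-bit.
- All stochastic components take explicit seeds; no wall-clock seeding.
- JC69 returns +inf at p ≥ 3/4; saturated pairs are excluded from means and
  replaced by the largest finite distance only where an algorithm needs a
  number (NJ).
- Negative NJ branch lengths are clamped to 0 with a warning, a standard
  practice.
- Newick serialisation uses 12 significant digits (round-trips to 1e-9);
  unknown bracket annotations survive round-trips verbatim. HPD serialisation
  as `[&hpd={lo,hi}]` is this package's own dialect.

## Known limitations

- The built-in NJ/MPL stand-ins are consistent but not statistically
  efficient; published-scale analyses should use the engine adapters.
- Dating by global scaling cannot express among-lineage rate variation; a
  single fast clade inflates every age above its calibration.
- The birth–death simulator's stopping rule biases branching times slightly
  relative to age-conditioned samplers.
- Clade tasks with a single exemplar in the backbone (singleton genera with
  additional unsequenced species) cannot be anchored and pass through
  ungrafted, with a warning.
- The indel overlay cannot insert, only delete.
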