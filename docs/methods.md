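# Methods

This note records the model, the parameter defaults and why they are what
they are, the synthetic generator's design, and the evaluation decisions.
It is the companion to the API docstrings; nothing here is needed to *use*
the package, but everything here is needed to *trust* it.

## 1. Literature filtering cascade

Input rows are semantic predications: `(pmid, subject_name, predicate,
object_name, subject_distance, object_distance)` with predicates
`STIMULATES`, `INHIBITS`, or `INTERACTS_WITH`. The cascade
(`run_filter_pipeline`) applies, in order:

1. **Distance filter** — keep rows where *both* argument–predicate distances
   are ≤ 1 (default `max_distance=1`). Extraction errors concentrate in
   long-range argument bindings; distance 1 means the argument is the
   syntactic head adjacent to the predicate. This is by far the most
   aggressive stage: on the packaged 13-pathway tables it keeps 27 % of rows
   pooled.
2. **De-duplication** — merge rows with the same (case-insensitive)
   `subject_name / predicate / object_name`, keeping the union of PMIDs.
   The merged record (`AggregatedPredication`) carries the PMID set because
   the later frequency stage needs document counts over *merged* mentions.
3. **Symbol normalization** — map raw names to canonical uppercase symbols
   through a `SymbolMap`; rows whose subject or object has no mapping are
   pruned (they are typically broad concepts, not genes). Records that
   collide after normalization are merged again.
4. **Document-frequency filter** — keep records cited by at least
   `min_docs=2` distinct PMIDs. A single-paper assertion is weak evidence;
   two independent citations is the smallest threshold that removes
   singletons without demanding a literature consensus.

`FilterReport` records the count after each stage and enforces monotonicity
at construction time, so a bookkeeping bug cannot silently produce an
impossible report.

## 2. Network assembly

Each surviving record contributes a directed edge `subject → object`. The
sign rule is conservative: +1 iff the merged predicates include `STIMULATES`
and not `INHIBITS`, −1 iff `INHIBITS` and not `STIMULATES`, else 0
(`INTERACTS_WITH` alone, or conflicting claims). Sign 0 edges still
constrain topology; they simply carry no directionality hint into reporting.

## 3. Weight model and training

The dynamical model is a single-layer linear-activation network over
normalized expression: `x̂_i(t+1) = Σ_j w_ij x_j(t)`, `w_ij ∈ [−1, 1]`, with
`w_ij` forced to 0 unless the literature network has edge `j → i`. Expression
is min–max normalized onto [−1, 1] (per gene by default) so the weight bounds
are meaningful across genes.

Each target gene is trained independently (the rows of `W` are decoupled) by
an elitist genetic algorithm:

- **Chromosome**: the target's weight row restricted to allowed positions.
- **Fitness** (minimized): summed squared one-step prediction error over all
  usable transitions (consecutive present arrays within a replicate).
- **Defaults**: population 2000, 200 generations, elite fraction 0.2
  (`max(1, ⌊0.2·pop⌋)` copied unchanged), per-locus mutation rate 0.0025,
  single-point crossover of two uniformly chosen parents, mutation by
  resampling the locus uniformly in [−1, 1].
- **Determinism**: gene *i* uses seed `rng_seed + i`, so per-gene results are
  independent of training order and of which other genes are trained.

The generation loop is vectorized across the population with numpy (einsum
fitness, vectorized crossover masks and mutation); the scalar `crossover` and
`mutate` operators exist and are property-tested for the same semantics.

**Mutation rate scaling.** The 0.0025 per-locus default is calibrated to
~78-locus chromosomes (≈0.2 expected mutations/child). On the small problems
used in tests (≤10 loci) that rate would mean almost no mutation, so
small-problem configurations raise the per-locus rate (e.g. 0.1 at 5 loci)
to keep the *per-child* mutation pressure in the same regime. This is a
deliberate re-parameterization, chosen before any outcomes were measured, not
tuning.

**Oracle.** Because the model is linear and the constraint set is a box, the
per-gene optimum is computable exactly with bounded-variable least squares
(`scipy.optimize.lsq_linear`, BVLS). `bounded_least_squares` is used in tests
as an independent oracle: the GA's converged fitness must be within 5 % of
the BVLS optimum on random instances. The oracle check uses random bounded
expression values rather than dynamics-generated data: on exactly realizable
data the optimum is 0 and a *relative* gap is undefined.

## 4. Evaluation

**Leave-one-out by time point.** For each held-out time `t* ∈ {2..T}`, the
model is retrained on all transitions not touching `t*`, then predicts
`x̂(t*) = W·x(t*−1)` from each replicate's present array at `t*−1`. The fold
RMSE pools squared deviations over genes × test replicates against the
**replicate-mean** observed value at `t*` — the mean is the best available
estimate of the underlying state, and scoring against it mirrors how
biological replicates of one time course are interpreted. Folds where no
training or test transitions exist (due to missing arrays) are skipped and
reported.

**Random baseline.** The comparison model draws, per target gene, `k`
regulators uniformly (default `k=10`; reduced-scale runs use `k` matched to
the literature network's density) and trains identically. Literature and
baseline runs share GA settings and seeds.

**Paired t-test.** Implemented directly (mean and sd of paired differences,
Student t p-value via `scipy.stats.t`) because degenerate cases need explicit
flags: zero-variance differences give p=1 if the mean difference is 0 and
p=0 otherwise. `scipy.stats.ttest_rel` serves as the test oracle in the
non-degenerate regime.

**Precision accounting.** `interaction_precision` counts predicted edges
(with `|w|` strictly above a threshold; threshold 0 means all trained edges)
found in a reference edge list, and predicted genes found among reference
nodes. Gene counts deliberately ignore the weight threshold — gene-level
membership is a topology property, not a weight property. The percentages in
`validation_percentages` are plain `100·count/total` rounded to one decimal.

## 5. Synthetic generator

`SyntheticSpec` defaults mirror the target study design: 78 genes, ~110-edge
backbone, 7 time points × 6 replicates with two missing arrays, Gaussian
noise sd 0.05. Components:

- **Planted network**: directed edges drawn i.i.d. with `edge_density`
  (self-loops allowed); weights have magnitude in [0.2, 1] (so every edge is
  identifiable above the noise floor) and sign negative with probability
  `inhibitory_fraction`; rows are rescaled to absolute sum ≤ 1, which keeps
  noise-free trajectories inside [−1, 1].
- **Dynamics**: `x(t+1) = W·x(t) + N(0, σ)`, clipped to [−1, 1] with the clip
  count reported (noise-free data must report 0 clips, and tests assert it).
- **Replicate design**: replicates share one initial state by default
  (`shared_initial_state=True`) and differ only through noise — replicate
  arrays of a single experiment measure the same biological time course.
  Independent initial states are available as an option and are used for
  noise-free identifiability fixtures, where shared noise-free replicates
  would be duplicate rows. This default matters: with independent initial
  states the replicate-mean target used by the LOO protocol is incoherent
  and the literature-versus-random comparison loses its meaning.
- **Predication emission**: each true edge yields a predication with distance
  1 and document frequency ≥ 2; spurious predications (rate relative to true
  edge count) draw distance and document frequency from configurable
  distributions; `alias_corruption_rate` replaces subject names with unmapped
  aliases. The generator returns the *planted* `FilterReport`, computed from
  the draws themselves, so the pipeline's report can be checked against
  ground truth by construction.

**Realism limits.** The generator produces linear dynamics with additive
Gaussian noise and a stationary network — no saturation, no measurement
batch effects, no predicate ambiguity beyond the three predicate types, and
document frequencies are independent of edge strength. It validates the
pipeline's correctness and discrimination ability, not biological fidelity.

## 6. Packaged data

Small TSV fixtures under `litgrn/data/` hold published summary tables used by
tests and the acceptance script: per-pathway filter-stage counts (13 rows),
a 78-symbol pathway gene list, experimental validation counts (55 of 92
interactions with correct sign and direction), interaction-precision counts
at four weight thresholds (147 of 520 at threshold 0), and a three-row probe
predication table whose filtering fate is documented (2 of 3 pass the
distance filter; none survive the frequency stage). All are a few hundred
bytes each.

## 7. Numerical and reproducibility notes

- All randomness flows through `numpy.random.default_rng` seeded from
  explicit config fields; same seed ⇒ identical results, including across
  the vectorized GA.
- Elite selection uses a stable sort, so ties break deterministically.
- Missing arrays are NaN in the value tensor plus a boolean presence mask;
  all statistics are computed over present entries only.
- The pipeline runner (`litgrn.app`) wraps each stage in a `PipelineError`
  naming the stage and writes a JSON manifest (inputs, parameters, seed,
  package and library versions) alongside the outputs.

## 8. Known limitations

- One-step linear dynamics; multi-step rollouts compound bias.
- The GA trains each gene against all transitions jointly; time-varying
  regulation is out of scope.
- Sign information from the literature is reported but not enforced as a
  constraint on the trained weight's sign (matching the reference method);
  sign agreement is an evaluation output, not a training input.
- Reference networks are consumed as plain edge lists; pathway-format
  (e.g. KGML) parsing is out of scope.
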