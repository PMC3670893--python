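# Methods

## The model

`polywasp` simulates the evolution of sex allocation in a polyembryonic,
haplodiploid parasitoid wasp of the *Copidosoma* type, in which

* each egg cleaves into a clone of genetically identical, same-sex adults
  (polyembryony), female clones being larger than male clones;
* fertilized (diploid) eggs become daughters and unfertilized (haploid) eggs
  sons, so virgin females can produce only sons;
* some female larvae develop into sterile soldier larvae that kill unrelated
  competitors within the host, biasing emergence against male clones that
  share a host with an unrelated female clone;
* hosts can be parasitized more than once (superparasitism), so broods may
  contain one or two (or more) clones of either sex.

The simulation is individual-based with discrete, non-overlapping
generations and no spatial structure or learning. One generation runs:

1. **Host renewal.** `host_count` fresh hosts appear.
2. **Oviposition.** For `lifespan` time steps, every living female is
   presented one uniformly random host. She accepts it iff its
   attractiveness `max(0, 1 − egg_count_influence · n_eggs)` strictly
   exceeds the `host_acceptance_threshold`, and then lays exactly one egg.
   Low thresholds admit already-parasitized hosts: the threshold is the
   model's superparasitism dial. Mated females draw the egg's sex from
   their strategy's sex-choice probability for the sensed host state
   (below); virgin females lay male eggs only.
3. **Brood resolution.** A host with more than `host_limit` eggs dies with
   all its eggs. Otherwise every egg yields a clone whose size is a normal
   draw (truncated at zero, rounded) from the survival distribution for its
   context: single-sex brood, mixed-sex brood among kin, or mixed-sex brood
   with unrelated competitors — the last context is where soldier
   interference suppresses male emergence.
4. **Mating.** A fraction `in_host_mating_ratio` of freshly emerged females
   mates with a uniformly chosen male of the same brood (both sexes emerge
   together); every male honours a lifetime cap of `virility` matings
   (`virgin_son_virility` for sons of virgins). Females still unmated after
   emergence mate with uniformly chosen males in the global dispersal pool,
   capacity permitting; leftovers stay virgin and will found all-male broods.
5. **Inheritance.** Daughters receive `w · father + (1 − w) · mother`
   component-wise over the sex-choice values (`w = strategy_inheritance`);
   sons carry their mother's strategy unchanged. There is no mutation
   operator, so every evolved value stays within the convex hull of the
   founding strategies' values.

**Host-state sensing.** A female senses the state of a host at one of three
information levels: *none* (empty vs. parasitized), *relatedness* (adds
whether occupants are kin — the egg's mother is the observer or one of her
sisters), or *sex_and_relatedness* (the full relatedness × occupant-sex
cross, ten states including the empty host). The strategy's sex-choice map
is keyed by these states. Relatedness spans one generation of maternal
lineage: eggs are related iff their mothers are the same individual or
sisters, which matches the field observation that co-parasitizing clones
are usually mothered by different, unrelated females.

## The tournament

An evolutionarily stable allocation is approximated by tournament selection:
125 random *viable* strategies (viability: a single-strategy population of
100 mated females persists for 50 generations) are split into 25 subsets of
five; each subset competes in one shared environment, seeded with 100 mated
females per strategy, until one matriline has held the whole population for
10 consecutive generations or a generation cap is reached. The 25 subset
winners re-compete in five subsets, and the five winners of those in one
final subset: 125 → 25 → 5 → 1. Each starting strategy is one uniform
scalar — the same sex-choice value in every host state — because the
evolving trait is a single sex-allocation random variable; component-wise
inheritance keeps blends scalar, so the winner is always interpretable as
one allocation value.

A round's winner is the strategy label with the highest long-term mean
population share (ties: final-generation count, then lowest index), and the
winning *strategy* is the clone-size-weighted mean sex-choice vector of that
label's females in the last generation it was alive — by fixation,
recombination has blended the founders, so the literal founder vector no
longer describes anyone. Because the paper-level quantity "the evolved sex
allocation" is ambiguous between the winner's strategy value and the egg
sex ratio the population actually realizes (virgin females lay male eggs
regardless of strategy), both are reported everywhere: the winner's
empty-host allocation and the realized primary sex ratio over the final 50
generations of the final round. Scenario-level directional checks use the
realized primary ratio, which is the literal definition of a primary sex
ratio (proportion of male eggs laid).

## Scenarios and the threshold sweep

* `symmetric` — all six survival contexts share the female single-sex
  parameters (equal proliferation and survival of the sexes) and mating
  happens on the natal host (`in_host_mating_ratio = 1`).
* `asymmetric_premating` — female developmental advantage (defaults below)
  with natal-host mating.
* `asymmetric_postmating` — the same asymmetry, all mating after dispersal.

Each scenario is swept over nine thresholds (0.05–0.85, step 0.1). With the
default `egg_count_influence = 0.3` and `host_limit = 3` the grid spans:
hosts accepted until they overcrowd and die (0.05 — the population
collapses, an output state, not an error), three eggs per host (0.15–0.35),
two (0.45–0.65), and single eggs only (0.75–0.85). A threshold of 1 or more
admits no host at all and the population goes extinct immediately. Reduced
sweeps use five thresholds spanning the three stable bands
(0.15, 0.35, 0.55, 0.65, 0.75).

## Parameter defaults and their provenance

| parameter | default | basis |
|---|---|---|
| female single-sex clone size | 45.7 ± 10.9 | published field estimate |
| male single-sex clone size | 32.4 ± 10.4 | published field estimate |
| female / male clone size, unrelated mixed brood | 40 ± 10 / 20 ± 8 | stand-in, calibrated so males ≈ 1/3 of mixed-brood adults (the published mixed-brood composition) |
| related mixed contexts | same as single-sex | soldiers spare kin |
| lifespan | 20 eggs | ≈ hosts parasitized on day one |
| host_limit | 3 eggs | stand-in |
| egg_count_influence | 0.3 | stand-in (with the grid above, spans no → heavy superparasitism) |
| strategy_inheritance | 0.5 | stand-in (unweighted parental blend) |
| virility / virgin_son_virility | 1 / 1 | stand-in, calibrated (below) |
| host_count / initial wasps | 200 / 100 per strategy | working scale (below) |

All values marked *stand-in* are not field measurements; they are the
package's defaults, chosen once and documented here, and every one is
overridable through the config file.

**Why virility 1.** The male mating cap is the single lever that decides
whether sex allocation can respond to the sexes' unequal developmental
prospects. If each male can fertilize many females (virility ≥ 2 at these
clone sizes), the global mating market never saturates and classic
Fisherian frequency dependence pins the evolved primary ratio at 0.5 in
every scenario — the survival asymmetry is post-investment mortality, which
sex-ratio theory says is *not* compensated. With virility 1, males are a
limiting resource: the market clears only when male adults roughly match
females, so the asymmetric scenarios (where male clones are small and
soldier-suppressed) evolve male-biased egg ratios that grow with
superparasitism, and the realized secondary ratio stays below both the
primary ratio and 0.5 — the qualitative pattern the model family is known
for. Virgins' sons share the cap of 1; a strictly lower value would bar
them from mating entirely.

**Known limitation.** The symmetric scenario's expected female-biased
allocation (local mate competition) does not emerge here: with virility 1
the market-clearing ratio in a symmetric world is exactly 0.5, and any
female bias creates virgins whose obligate sons pull the realized ratio
back; with higher virility, the unconditional global dispersal-mating
mop-up restores 0.5 everywhere. Genuine LMC bias requires patch-limited
male mating opportunities, which this lifecycle (all unmated females enter
a global dispersal pool) does not contain. The winner's *strategy*
allocation in the symmetric scenario is female-biased (≈ 0.36–0.49); the
realized egg ratio is not. The relevant scenario test asserts the expected
direction and therefore fails by design rather than being weakened.

## The synthetic brood census

`generate_brood_census` emulates only the statistical structure the census
estimators assume: hosts independently receive one or two eggs, egg sexes
are i.i.d. Bernoulli draws from a true primary ratio, and emergence counts
come from the same survival distributions as the simulator (mixed broods
use the unrelated-mixed context). Broods are classified by the sexes that
*emerge* — a mixed-egg brood whose male clone yields no adults is observed
as all-female, exactly the censoring a real census suffers — and hosts with
no emergers are unobserved. It deliberately omits everything else the full
simulator has (no evolution, no soldier bookkeeping beyond the survival
contexts, no mating): passing estimator tests on this generator shows the
estimators are consistent under their own assumptions, not that real
censuses satisfy those assumptions.

The primary-ratio estimator assumes a fraction `p_super` of single-sex
broods carried two same-sex eggs and every mixed brood one egg of each sex;
the default algebra uses the expectation form (each single-sex brood counts
`1 + p_super` eggs), with an integer-allocation variant
(`round(p_super · n)` double broods per class) available, since the
assumption fixes the correction but not the arithmetic.

## Numerical and design choices

* Clone sizes: normal draw clamped at zero, then rounded half-even — with
  zero SD the sampler is deterministic (`round(mean)`).
* Host presentation: one uniform host per female per step, with
  replacement across females; within a step females act in a random order
  and an unacceptable presentation simply consumes the step.
* Mate choice is uniform over individual males (so male cohorts draw mates
  in proportion to head count), with hard virility caps enforced by
  redistributing the excess among males with capacity left; the order of
  female mating attempts is randomized.
* Population state is held as cohorts of identical wasps (a clone, or the
  mated/virgin split of one); semantics are individual-level and an
  exhaustive per-individual oracle checks a generation exactly in the
  degenerate (zero-variance, 0/1-probability) regime.
* All randomness flows from one `numpy.random.Generator`; replicate and
  round seeds derive from the user seed via `SeedSequence.spawn`, so runs
  are bit-reproducible.
* Extinction stops a run and is flagged, never raised, except inside a
  tournament round where the loss of every competitor is an error naming
  the subset.
* Working scale: 200 hosts and 100 founders per strategy keep one
  competition round's populations around 10⁴–3·10⁴ adults, large enough
  for selection to dominate drift within a 100–500 generation round while
  a full three-round tournament stays interactive. Viability screening
  runs at 60 hosts; persistence, not dynamics, is what it measures.
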