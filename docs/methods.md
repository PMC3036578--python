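# Methods

## The model

`netherit` simulates a closed population of sexually reproducing
hermaphrodites whose single quantitative trait is encoded by one of two
genotype–phenotype maps (GPMs):

**Network GPM.** The trait is produced by a single-input Boolean gene
regulatory network of `n` genes. Gene 0 (the root) carries a heritable state
bit; every other gene `i` carries a *gene block* — the index of its single
upstream regulator (`head(i)`, constrained to `{0..i-1}`) and a function bit
(1 = activator, 0 = repressor). States propagate in index order by an XNOR
rule: a gene is on exactly when its regulator's state equals the function
bit. The phenotype is the on-fraction of the *terminal* genes (out-degree
zero) scaled to the environmental range (140 trait units): with `T`
terminals of which `T_on` are on, `z = 140 * T_on / T`. Small networks thus
resolve the trait coarsely (steps of `140/T`); the terminal set itself is
heritable and evolvable. The mutational target has `2n - 1` elements
(`n-1` heads, `n-1` function bits, the root state).

**Linear GPM.** A purely additive control: `n` Boolean loci,
`z = 140/n * (number of 1 alleles)`. Its mutational target is `n` elements,
so linear designs double the mutation rate to equalise the genome-wide rate
against the network's `2n - 1` target.

**Topology.** Networks are grown gene by gene. Under `random` attachment the
regulator of gene `i` is uniform on `{0..i-1}`; under `scale_free` it is
drawn by lottery with probability proportional to (out-degree + 1). The +1
smoothing defines the lottery when all degrees are zero and keeps
degree-zero genes reachable; the head-index ordering makes acyclicity a
structural invariant that survives any sequence of mutation and
recombination, with no cycle checks needed.

**Life cycle** (non-overlapping generations, order fixed):

1. *Reproduction.* Every individual initiates exactly one mating with a
   uniformly drawn other individual (selfing excluded; an individual may
   additionally be chosen as a partner). Offspring per mating ~
   Poisson(λ = 1.5). Offspring chromosomes are built by block-wise
   recombination — the first element (root state) comes from a fair-coin
   starting parent and a switch to the other parent occurs with probability
   `r` at each subsequent element; heads and functions of a gene move
   jointly — followed by per-element mutation with probability `mu`
   (function/root bits flip; a head redraws uniformly among the lower-index
   genes excluding the current one, so every head mutation changes the
   genotype; gene 1, whose only possible regulator is gene 0, is the single
   immutable head).
2. *Parental death.* All parents die.
3. *Viability selection.* Each offspring survives iff `RF >= U`,
   `U ~ Uniform(0,1)`, with `RF = exp(-(|E - z| / s) ** omega)` against the
   current environment `E`. `omega` (1.5–2.5) is the width exponent — the
   function is Gaussian at `omega = 2`, and beyond the scale `s` a larger
   `omega` means lower tolerance for mismatch; `s` defaults to 10 trait
   units and is configurable. The generalized-Gaussian form was chosen
   because it reconciles calling `omega` both a "width" and an "exponent"
   while preserving the stated tolerance direction.
4. *Culling.* A uniformly random subset of at most `K = 500` individuals
   remains ("below K" is read as "at most K"; ties broken by the cull RNG).

**Environment.** A single driver variable, initial value 70 (the centre of
the trait range). Schedules: constant; a single downward step of 20 or 30
units at a fixed generation (251 after a 250-generation canalization
period); or a step triggered one generation after the population's additive
variance first reaches a threshold (5/10/20), with a hard cutoff (default
1500 generations) for runs whose threshold is never reached — those runs are
returned flagged as truncated, not raised as errors.

## Observables

Per generation, on the post-culling population: size, mean phenotype,
phenotypic variance `V_P` (sample variance, ddof 1), heritability `h²` as
the OLS slope of offspring phenotype on recorded mid-parent phenotype (the
mid-parent regressor needs no doubling), and `V_A = h² V_P`. Degenerate
regressions (< 3 pairs, zero mid-parent variance) yield NaN, which is
excluded — never zero-filled — from window means and trend regressions; the
last defined `V_A` is carried forward for trigger checks. Raw slopes are
recorded alongside a clamped copy (`[0, 1.5]`) that guards the variance
products against pathological slopes in tiny populations. Founders have no
mid-parent; for the *linear* architecture only, the founder generation's
`h²` is recorded as 1 and `V_A = V_P` — with iid loci and no environmental
variance this is an identity of the model, not an estimate — so variance
decay is measured from the variance the population actually starts with.
Network founders keep `h²` undefined.

Rates of change `dV_A/dt`, `dV_P/dt` are OLS slopes against generation over
the canalization window. Recovery time after a change at generation `c` is
measured against the baseline mean population size of generations
`[c-50, c-1]`: the first generation strictly after `c` whose size is at or
above the baseline (ties count as recovered; exact equality of a mean is
measure-zero). Extinct or horizon-capped runs are "never recovered".

## Epistasis assay

On a random wild-type network, two distinct point mutations are drawn from
one class — *function* (bit flip, genes 1..n-1) or *topology* (head redraw,
genes 2..n-1) — giving wild type, two single mutants, and the double
mutant. All four are scored by the viability function against `E = 70`,
`omega = 2`, `s = 10` (the assay's reference conditions; all configurable),
and `epsilon = w_ab - w_a w_b` on raw fitnesses. A wild-type-normalised
variant (every fitness divided by `w_wt`) is available but off by default.
Because fitnesses are bounded by 1, a phenotypically silent mutation pair on
a sub-optimal wild type gives `epsilon = w - w² > 0` exactly — the assay has
a structural positive bias that the experiment quantifies rather than
removes. The factorial crosses six sizes {8, 16, 32, 64, 128, 256} (the five
main-design sizes plus 8 as the sixth level, flagged in output metadata),
two topologies, and the two mutation classes; group summaries divide epsilon
by its within-size standard deviation to homogenise variances (the sign of
the size trend differs between weighted and raw means, so both are
reported). Mixed-class mutation pairs are excluded. |epsilon| below 1e-12
counts as no epistasis. The heavy-tailed-error GLM treatment of epistasis is
deliberately replaced by these weighted summaries plus OLS — an
approximation, noted as such.

## Factorial designs and analysis

`network_main`: 5 sizes × 2 topologies × 3 mutation rates (1e-3/1e-4/1e-5)
× 2 recombination rates (0.05/0.5; 0.25 available) × 2 width exponents
(1.5/2) × 2 change magnitudes (20/30), 3 replicates = 720 runs.
`linear_main`: topology dropped, mutation rates doubled, 360 runs.
`va_trigger`: the network crossing with thresholds {5, 10, 20} replacing the
fixed change generation, 1 replicate = 720 runs (the published per-cell
counts do not factor uniquely; the full crossing at one replicate is this
package's choice). Every run's seed derives from the design master seed, so
a design is bit-reproducible end to end.

Variance partitioning is a sequential (type-I) ANOVA on the log-transformed
response (heritability distributions are right-skewed), terms entered in the
documented order (size, topology, recombination, pre-change `V_A`,
size × `V_A`); percent of total SS is order-sensitive, so the order is part
of the analysis definition. Effect directions are signs of the response's
correlation with a numeric coding of each term (size treated as
continuous). Model-selection narratives are reduced to a single AIC
comparison between a reduced and a full model.

## Desk scale

Routine verification and the acceptance script run the designs at a reduced
"desk" scale chosen once: population 250, one replicate per cell, horizon
250 generations for canalization-period analyses, or horizon 1000 with
early stop once recovery is observed for post-change analyses; the
epistasis experiment uses ≥200 networks per cell. Scale metadata is written
into every summary. At desk scale, runs that go extinct during canalization
(a real outcome of this model, concentrated in small networks with free
recombination) are excluded from pre-change ANOVAs; never-recovering runs
are censored at the maximum post-change duration in recovery models, since
they are informative about slow recovery, not missing.

## What the generator does and does not emulate

Synthetic inputs are the simulation itself: random founder networks (fair
function bits and root states — initial bit frequencies are an open choice),
iid founder loci for the linear GPM, and the environment schedules above.
The model removes all direct environmental effects on the phenotype, so
measured heritabilities are upper bounds on what an otherwise identical
noisy trait would show; it has one regulator per gene, no feedback, no
dynamics/attractors, one patch, no age structure, and binary alleles.
Passing tests therefore speak to the behaviour of this idealised GPM class,
not to any particular organism's regulatory biology.

## Numerical choices and known limitations

- RNG: NumPy PCG64; one master seed per run spawns named substreams
  (founders, mating, selection, culling) so single stages can be perturbed
  in isolation. Derived seeds stay below 2^31.
- Scalar chromosome operators are plain reference implementations;
  population steps run through vectorised array kernels. Tests pin the two
  routes to the same semantics (deterministic cases and distributional
  checks).
- `h²` clamping to [0, 1.5] biases `V_A` slightly downward in tiny
  populations; raw slopes are kept in the output for sensitivity checks.
- Sign classification of epsilon uses an absolute 1e-12 tolerance; fitness
  underflow (mismatch beyond ~53 trait units at the default width) maps to
  "no epistasis" rather than spurious signs.
- The positive/negative epistasis split is sensitive to unmodelled details
  of network initialization; under the defaults here it measures roughly
  81% / 13% with ~95% directional, and the split (unlike the directional
  fraction) should not be over-interpreted.
- Population persistence is emergent: per-capita growth is 1.5 × mean
  viability, so populations with large segregation variance relative to the
  selection scale sit well below `K` and can go extinct even in a constant
  environment. This is a property of the stated fitness form, not a
  numerical artifact.
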