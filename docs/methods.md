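# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage of the pipeline, and what the synthetic generators do and
do not emulate.

## Serial-passage population model

The evolving culture is modelled as a discrete Wright–Fisher population whose
generations are equated with population doublings (the experiment reports
time in doublings). Each genotype *g* — a set of mutation identifiers, the
founder being the empty set — has a true growth rate µ*g* (h⁻¹); selection
weights are proportional to µ, so the per-generation selection coefficient
between two genotypes is ln(µ₁/µ₀) and, with drift disabled, a two-genotype
competition follows the logistic closed form
f(t) = f₀e^{st}/(1 − f₀ + f₀e^{st}) exactly (asserted to 1e−6). Drift is
multinomial resampling at effective size *N* (default 20 000), giving
per-generation frequency variance f(1−f)/N (checked to 10% over 1000 seeds).

Innovation happens in two ways: random events at a per-individual rate that
convert a genotype into one of its minimal supersets present in the fitness
map, and scheduled introduction events (genotype → generation, frequency)
used by the default lineage scenario so that clone sweeps are staggered and
reproducible. One *event* introduces one new clone; the clone may carry
several linked marker mutations (as a deletion detected as several variant
rows would), which is what makes clone-membership recovery a non-trivial
clustering problem. Cheater genotypes get a fitness bonus linear in the
current abundance of designated lysing genotypes, which themselves lose a
fixed fraction per generation — a minimal stand-in for cross-feeding on
lysate nutrients. No back-mutation; bottleneck structure of the passages is
not modelled (the experiment does not report it), only the doubling clock.

Mutation frequencies are reported at the experiment's sampled doublings
(18, 27, 31, 38, 44, 63, 82, 102, 121, 151), with optional additive Gaussian
measurement noise (σ = 0.02 in tests, the scale of frequency error expected
at ~100× sequencing coverage) clipped to [0, 1].

The default scenario has seven genotypes in two competing lineages — a
four-step nested chain (growth rates 0.30 → 0.36 → 0.42 → 0.50 → 0.58 h⁻¹)
and a two-step competitor (0.41, 0.445 h⁻¹) that rises early and is later
outcompeted — chosen so that adjacent clones are separated by ≥0.4 in maximum
frequency gap at the sampled generations. What passing recovery tests shows:
membership clustering and nesting work when clones are separated on the
sampling grid; they say nothing about clones that sweep faster than the
sampling interval, which no method could distinguish from their parents.

## Lineage inference

Filtering keeps a mutation if it was observed (frequency > 0) at ≥2
consecutive timepoints **and** exceeded 10% at least once, or if its gene
already contains a directly retained mutation (rescue); an `"or"` predicate
combining the clauses disjunctively is available, since the study's two
descriptions of the rule differ. The filter is idempotent and logs the rule
applied to every row.

Clustering uses average linkage on d = 1 − Pearson r with two guards: pairs
whose trajectories differ by more than 0.15 in maximum absolute frequency are
never merged (correlated but offset trajectories are parent/child, not one
clone), and zero-variance trajectories become singletons. The merge threshold
is 0.15 on correlation distance.

Nesting: clone B may sit inside clone A iff f_B(t) ≤ f_A(t) + ε for all
sampled t, with ε = 0.05 absolute frequency (the tolerance absorbs both
clones' measurement noise). A fixed precedence (descending total abundance)
breaks mutual-containment ties and guarantees acyclicity. Because a greedy
parent assignment can dead-end on noisy data, the final forest is found by a
bounded exhaustive search over each clone's candidate parents (nearest
enclosing first, virtual root last) for the first assignment satisfying every
sibling-sum constraint Σ children ≤ parent + ε; with ≤8 clones the search
space is tiny. If no assignment exists the inference raises, naming the
clones — at noise σ = 0.02 this happens in a small minority (<10%) of runs
and is the designed behaviour of the tolerance, not a failure mode to be
silently papered over.

The Muller matrix interpolates clone abundances linearly between sampled
generations, prepends an all-ancestor state at generation 0, orders bands
depth-first by emergence, sets each clone's own band to abundance minus the
sum of its children (clipped at 0), and renormalises columns, which therefore
sum to 1 to 1e−9 by construction.

Amplification calling uses 0-based half-open windows; baseline = genome-wide
median depth (≥20 windows required); candidate windows at ≥1.5× baseline are
merged across gaps ≤5 kb and reported when ≥10 kb (defaults), with copy ratio
= median in-interval depth / baseline.

## Growth-rate estimation

A dilution event is a between-sample relative OD drop >5% (the instrument
dilutes ~12% when crossing the upper setpoint, so the threshold separates
dilutions from noise). A segment ending in a dilution is one cycle; a
dilution-free stretch is cut into windows of ≤2 h (the protocol's "1–2 h"
resolved to 2 h, configurable). Each cycle with ≥3 points is fitted by OLS on
(t, ln OD) — equivalent to a single-exponential fit and numerically stable —
and cycles with R² < 0.9 are dropped with a warning (no quality filter is
stated in the protocol; this guards against cycles straddling artifacts).
The vial's µ is the median over cycles (breakdown point: 1 outlier in 7),
with a percentile bootstrap CI on the median; fewer than 7 cycles triggers a
warning. Per-vial medians are summarised across vials rather than pooling
cycles across vials.

Phase detection computes windowed ln-OD slopes (windows never span a
dilution), smooths them with a 5-point moving average, and finds the first
sustained negative stretch: everything before is "fast", the negative
stretch is "decline", and the remainder "steady". Phase-filtered estimation
uses the last non-decline phase and raises on a decline-only trace. A
monotone trace is a single phase.

CFU/mL = 3.52 × 10⁸ × OD600 (the study's linear calibration; the constant is
a parameter).

## B6 content and accumulation rate

Standard curves are least-squares polynomials (degree 1 for the 4-PLA
fluorescence assay over 0–40 nM; degree 2 for the DNA and protein assays),
rejected if non-monotone over the calibrated range. Inversion is closed-form
for lines; for quadratics the root inside the calibrated concentration range
is chosen, ties toward the smaller concentration. Responses below the blank
are clipped to zero concentration with a warning; responses above the fitted
range raise rather than extrapolate.

Dilutions are explicit ledgers of (step, factor) pairs; the product of a
ledger converts a measured concentration back to the sample. The bundled
presets encode the assay's successive additions — lysate: 200 µL + 20 + 5 +
165 + 60 + 20 µL (net 470/200 = 2.35×); spent medium: 195 µL + 22 + 8 + 165 +
60 + 20 µL (net 470/195 ≈ 2.41×) — because the protocol gives volumes, not a
combined factor. Ledger application/back-correction round-trips to 1e−12.

Content: nM (= pmol/mL) × ledger product × processed volume (mL), lysate and
medium parts summed, normalised to 10⁹ CFU. Accumulation rate = content ÷
doubling time with doubling time = ln 2/µ; the rate's CI propagates relative
errors of content and µ in quadrature. The pipeline reports measured rates
only and never imputes a rate for a strain that was not assayed; the
"parental proxy" in the demo is a strain whose growth matches the founder's,
mirroring how the parental estimate was argued.

## Landscape statistics

Welch's t with Welch–Satterthwaite df is computed for all 120 pairs among the
16 genotypes. The Dunnett T3 adjusted p refers each |t| to the studentized
maximum modulus (SMM) distribution with that pair's df and family size m:

P(SMM ≤ q) = ∫₀^∞ [2Φ(qu) − 1]^m f_U(u) du,  U = χ_ν/√ν,

evaluated by Simpson quadrature on 513 nodes over u ∈ [0, 1 + 15/√ν]
(vectorised and chunked; with m = 1 this reduces exactly to the two-sided t
probability, asserted to 1e−5). The family defaults to all 120 pairs,
matching how statistical groups are displayed; a forward-edges-only family
(m = 32) is available. A Šidák fallback 1 − (1−p)^m is provided; it agrees
with the SMM within 2% only for large df (≳100) — at the study's df (~10–20)
the SMM is substantially less conservative, which is precisely why T3 is used
there. Under a null landscape (16 identical groups, 8 replicates) the
familywise error of the all-pairs pipeline is ~5% at α = 0.05 (measured
4.3–5.2% over 2000 simulated families).

Compact letter displays use insert-and-absorb: start with one letter holding
all genotypes; for each significant pair split every letter containing both
and absorb subset letters. Consistency (significant pairs share no letter;
non-significant pairs share at least one) is oracle-checked against
brute-force maximal cliques of the non-significance graph.

A step is *accessible* unless it is a significant *decrease* (the study
dashes only significant decreases); a strict mode requiring a significant
increase is available. A genotype is accessible if at least one incoming
forward step is accessible. All L! orderings are enumerated (guarded at
L ≤ 10) and annotated step by step. The greedy best trajectory takes the
largest mean-µ increase at each step, ties broken by locus order with a
warning.

Multiplicative epistasis: expected fold = Π over loci of (single-mutant mean
µ / founder mean µ); observed fold = full-mutant mean µ / founder mean µ.
Both the literal product and the largest single fold (the "others neutral"
reading) are reported, since the study's stated expectation does not
disambiguate them; folds use means, not medians, with a replicate bootstrap
CI on the observed/expected ratio.

## Study-condition landscape

The reference fitness map encodes the growth-rate structure the study
reports: founder 0.0094 h⁻¹; the quadruple mutant 0.30 h⁻¹ (32-fold);
*gapA\** alone 4-fold up; *rpoS\** added to *gapA\** 4-fold down (the
cheater); the *gapA\* rpoS\** Δ3.8 triple at 0.10 h⁻¹ with *rpoC\** giving a
further 3-fold; the alternative triple on the best trajectory already at the
quadruple's rate; the other single and double mutants within ~5% of the
founder. Exactly two steps (adding *rpoS\** or *rpoC\** to the *gapA\**
single) are significant decreases, reproducing "30 of 32 steps accessible"
with all 16 genotypes reachable. Replicates are lognormal with mean equal to
truth, n = 10 per genotype and CV = 0.1, matching the reported 7–13
biological replicates and their dispersion. The supplementary per-genotype
replicate table was not available to this package; all landscape statistics
are therefore validated on this reconstruction, and the acceptance summary
averages over 16 independent replicate draws (medians for the integer
counts).

## Problem sizes and limitations

Default problem sizes: 50 simulated populations for lineage recovery, 200
noisy traces for growth-rate recovery, 2000 null families for the type-I
check, 16 landscape draws for the accessibility/epistasis summaries — sizes
at which every summary statistic is stable to well within its tolerance.

Known limitations: the population model has no spatial structure, no
chemostat dynamics and no explicit bottlenecks; sequencing noise is additive
Gaussian rather than binomial read sampling; the three-phase trace generator
uses piecewise-constant rates rather than a mechanistic lysis model; the
cheater coupling is a linear abundance bonus, a qualitative stand-in; and
amplification detection assumes an otherwise flat coverage profile. Passing
tests demonstrate correctness of the estimators under these structured
synthetic conditions, not performance on raw sequencing artifacts
(mapping bias, coverage waviness) that upstream tools handle.
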