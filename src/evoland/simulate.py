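"""Synthetic-data generators with the statistical structure of the experiment.

Every downstream stage of the pipeline can be exercised without external data:

* :func:`simulate_serial_passage` — a discrete Wright-Fisher serial-passage
  population (generations equated with population doublings) with selection,
  drift, innovation events, optional cheater cross-feeding and lysis of
  fragile genotypes; returns a mixed-population mutation-frequency table plus
  the ground-truth lineage forest.
* :func:`simulate_turbidostat_trace` — a turbidostat OD600 sawtooth held
  between two setpoints, with multiplicative lognormal noise and an optional
  fast/decline/steady three-phase prefix typical of cofactor-starved strains.
* :func:`simulate_landscape_replicates` — heteroscedastic (lognormal)
  replicate growth rates around a true genotype->mu map.
* :func:`simulate_assay_plate` — linear or quadratic standard-curve plate
  readings with Gaussian noise.

:func:`reference_fitness_map` encodes the study's four-locus landscape from
the growth-rate fold-changes reported for the evolved strain and its
intermediates; :func:`default_lineage_config` builds a clonal-interference
scenario with nested lineages sampled at the experiment's generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import ODTrace
from .landscape import DEFAULT_LOCI, Genotype, LandscapeMeasurement, all_genotypes
from .lineage import Clone, LineageForest

__all__ = [
    "SAMPLE_GENERATIONS",
    "SimulationConfig",
    "TraceConfig",
    "simulate_serial_passage",
    "simulate_turbidostat_trace",
    "simulate_landscape_replicates",
    "simulate_assay_plate",
    "reference_fitness_map",
    "reference_accumulation_truth",
    "default_lineage_config",
]

#: Generations (population doublings) at which population gDNA was sampled.
SAMPLE_GENERATIONS = (18.0, 27.0, 31.0, 38.0, 44.0, 63.0, 82.0, 102.0, 121.0, 151.0)

GenotypeKey = frozenset


def _as_key(genotype) -> GenotypeKey:
    if isinstance(genotype, str):
        parts = [p for p in genotype.split(";") if p]
        return frozenset(parts)
    return frozenset(genotype)


# ---------------------------------------------------------------------------
# serial passage


@dataclass
class SimulationConfig:
    """Configuration of the Wright-Fisher serial-passage simulation.

    ``fitness_map`` maps genotypes (sets of mutation identifiers; the founder
    is the empty set) to true growth rates mu (h^-1); selection weights are
    proportional to these values, so the per-generation selection coefficient
    between two genotypes is ln(mu1/mu0).  Innovation events convert a
    genotype into one of its minimal supersets in the map (one event per
    innovation; an event may carry several linked marker mutations, as a large
    deletion detected as multiple rows would).  Cheater genotypes receive a
    fitness bonus linear in the current abundance of lysing genotypes; lysing
    genotypes lose ``lysis_rate`` of their individuals each generation.
    """

    fitness_map: dict
    sample_generations: tuple[float, ...] = SAMPLE_GENERATIONS
    pop_size: int = 10_000
    mutation_rate: float = 0.0
    initial_frequencies: dict | None = None
    gene_map: dict | None = None  # mutation id -> gene name
    introductions: dict | None = None  # genotype -> (generation, frequency)
    cheater_genotypes: tuple = ()
    lysing_genotypes: tuple = ()
    cross_feed_boost: float = 0.0
    lysis_rate: float = 0.0
    drift: bool = True
    measurement_noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.fitness_map = {_as_key(g): float(mu) for g, mu in self.fitness_map.items()}
        if frozenset() not in self.fitness_map:
            raise ValueError("configuration error: fitness_map must contain the founder")
        if any(mu <= 0 for mu in self.fitness_map.values()):
            raise ValueError("all fitness values must be positive")
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        gens = tuple(float(g) for g in self.sample_generations)
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("sample_generations must be strictly increasing")
        self.sample_generations = gens
        if not 0 <= self.lysis_rate < 1:
            raise ValueError("lysis_rate must be in [0, 1)")
        self.cheater_genotypes = tuple(_as_key(g) for g in self.cheater_genotypes)
        self.lysing_genotypes = tuple(_as_key(g) for g in self.lysing_genotypes)
        if self.initial_frequencies is not None:
            init = {_as_key(g): float(f) for g, f in self.initial_frequencies.items()}
            unknown = [g for g in init if g not in self.fitness_map]
            if unknown:
                raise ValueError(f"initial frequencies for unknown genotypes: {unknown}")
            if not math.isclose(sum(init.values()), 1.0, abs_tol=1e-9):
                raise ValueError("initial frequencies must sum to 1")
            self.initial_frequencies = init
        if self.introductions is not None:
            intro = {
                _as_key(g): (int(round(gen)), float(f))
                for g, (gen, f) in self.introductions.items()
            }
            unknown = [g for g in intro if g not in self.fitness_map]
            if unknown:
                raise ValueError(f"introductions for unknown genotypes: {unknown}")
            if any(f <= 0 or f >= 1 for _, f in intro.values()):
                raise ValueError("introduced frequencies must be in (0, 1)")
            self.introductions = intro

    def minimal_supersets(self, g: GenotypeKey) -> list[GenotypeKey]:
        supers = [k for k in self.fitness_map if k > g]
        return [
            k for k in supers if not any(g < other < k for other in supers)
        ]


def _parent_of(key: GenotypeKey, fitness_map: dict) -> GenotypeKey | None:
    """Largest proper subset of *key* present in the map (unique for trees)."""
    subs = [k for k in fitness_map if k < key]
    if not subs:
        return None
    best = max(subs, key=lambda k: (len(k), sorted(k)))
    ties = [k for k in subs if len(k) == len(best)]
    if len(ties) > 1:
        raise ValueError(
            f"ambiguous lineage: genotype {sorted(key)} has multiple parents"
        )
    return best


def simulate_serial_passage(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, LineageForest]:
    """Run the serial-passage simulation.

    Returns a mutation-frequency table (one row per mutation; one column per
    sampled generation holding its summed frequency across all genotypes
    carrying it) and the ground-truth lineage forest (one clone per
    non-founder genotype, with abundances including its descendants).
    """
    rng = np.random.default_rng(config.seed)
    founder = frozenset()
    keys = sorted(config.fitness_map, key=lambda k: (len(k), sorted(k)))
    idx = {k: i for i, k in enumerate(keys)}
    mu = np.array([config.fitness_map[k] for k in keys])
    n = len(keys)

    freq = np.zeros(n)
    if config.initial_frequencies is None:
        freq[idx[founder]] = 1.0
    else:
        for k, f in config.initial_frequencies.items():
            freq[idx[k]] = f

    extensions = {k: [idx[s] for s in config.minimal_supersets(k)] for k in keys}
    lysing = np.array([k in config.lysing_genotypes for k in keys])
    cheater = np.array([k in config.cheater_genotypes for k in keys])

    sample_gens = np.array(config.sample_generations)
    sample_at = np.rint(sample_gens).astype(int)
    horizon = int(sample_at.max())
    recorded = np.zeros((len(sample_gens), n))
    if 0 in sample_at:
        recorded[sample_at == 0] = freq

    for gen in range(1, horizon + 1):
        w = mu.copy()
        if config.cross_feed_boost and cheater.any():
            w = w * np.where(cheater, 1.0 + config.cross_feed_boost * freq[lysing].sum(), 1.0)
        if config.lysis_rate and lysing.any():
            w = w * np.where(lysing, 1.0 - config.lysis_rate, 1.0)
        p = freq * w
        total = p.sum()
        if total <= 0:
            raise RuntimeError("population went extinct")
        p = p / total
        if config.drift:
            freq = rng.multinomial(config.pop_size, p) / config.pop_size
        else:
            freq = p
        if config.mutation_rate > 0:
            delta = np.zeros(n)
            for k in keys:
                i = idx[k]
                if freq[i] <= 0 or not extensions[k]:
                    continue
                if config.drift:
                    count = int(round(freq[i] * config.pop_size))
                    n_mut = rng.binomial(count, config.mutation_rate)
                    if n_mut == 0:
                        continue
                    targets = rng.choice(extensions[k], size=n_mut)
                    moved = n_mut / config.pop_size
                    delta[i] -= moved
                    for tgt in targets:
                        delta[tgt] += 1.0 / config.pop_size
                else:
                    moved = freq[i] * config.mutation_rate
                    delta[i] -= moved
                    share = moved / len(extensions[k])
                    for tgt in extensions[k]:
                        delta[tgt] += share
            freq = freq + delta
        if config.introductions:
            for k, (when, f) in config.introductions.items():
                if when == gen:
                    parent = _parent_of(k, config.fitness_map) or founder
                    take = min(f, freq[idx[parent]])
                    freq[idx[parent]] -= take
                    freq[idx[k]] += take
        hit = sample_at == gen
        if hit.any():
            recorded[hit] = freq

    # mutation frequencies: sum over genotypes carrying each mutation
    mutations = sorted({m for k in keys for m in k})
    gene_map = config.gene_map or {}
    rows = []
    for mi, m in enumerate(mutations):
        carrier = np.array([m in k for k in keys])
        traj = recorded[:, carrier].sum(axis=1)
        if config.measurement_noise_sd > 0:
            traj = traj + rng.normal(0.0, config.measurement_noise_sd, traj.size)
        traj = np.clip(traj, 0.0, 1.0)
        rows.append(
            {
                "mutation_id": m,
                "gene": gene_map.get(m, m),
                "position": mi + 1,
                **{g: traj[j] for j, g in enumerate(sample_gens)},
            }
        )
    table = pd.DataFrame(rows)

    forest = LineageForest(generations=sample_gens)
    for k in keys:
        if k == founder:
            continue
        carriers = np.array([k <= other for other in keys])
        abundance = recorded[:, carriers].sum(axis=1)
        parent = _parent_of(k, config.fitness_map)
        parent_id = None if parent in (None, founder) else ";".join(sorted(parent))
        forest.clones[";".join(sorted(k))] = Clone(
            clone_id=";".join(sorted(k)),
            mutations=tuple(sorted(k - (parent or frozenset()))),
            parent=parent_id,
            abundance=abundance,
        )
    return table, forest


# ---------------------------------------------------------------------------
# turbidostat traces


@dataclass
class TraceConfig:
    """Configuration of a simulated turbidostat OD600 trace.

    ``phase_profile`` optionally prepends a three-phase slow-grower prefix:
    ``(fast_mu, decline_rate, slow_mu)`` with ``phase_durations = (fast_h,
    decline_h)``; the steady phase at ``slow_mu`` then runs to ``duration``.
    Noise is multiplicative lognormal with log-sd ``noise_sd``.
    """

    true_mu: float = 0.3
    od_floor: float = 0.14
    od_ceiling: float = 0.16
    dilution_factor: float | None = None  # OD after / OD before a dilution
    sampling_interval: float = 0.1
    duration: float = 24.0
    noise_sd: float = 0.0
    phase_profile: tuple[float, float, float] | None = None
    phase_durations: tuple[float, float] = (4.0, 6.0)
    vial_id: str = "vial"
    medium: str = "M9/glucose"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.od_floor < self.od_ceiling:
            raise ValueError("need 0 < od_floor < od_ceiling")
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("duration and sampling_interval must be positive")
        if self.dilution_factor is None:
            self.dilution_factor = self.od_floor / self.od_ceiling
        if not 0 < self.dilution_factor < 1:
            raise ValueError("dilution_factor must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_turbidostat_trace(config: TraceConfig) -> ODTrace:
    """Exponential growth between setpoints with instantaneous dilutions."""
    rng = np.random.default_rng(config.seed)
    dt = config.sampling_interval
    times = np.arange(0.0, config.duration + dt / 2, dt)

    if config.phase_profile is not None:
        fast_mu, decline_rate, slow_mu = config.phase_profile
        fast_h, decline_h = config.phase_durations
        segs = [(fast_mu, fast_h), (-abs(decline_rate), fast_h + decline_h), (slow_mu, np.inf)]
        boundaries = [fast_h, fast_h + decline_h]
    else:
        segs = [(config.true_mu, np.inf)]
        boundaries = []

    def mu_at(t: float) -> float:
        for m, until in segs:
            if t <= until:
                return m
        return segs[-1][0]

    od = np.empty_like(times)
    od[0] = config.od_floor
    latent = config.od_floor
    dilutions = []
    for k in range(1, times.size):
        latent *= math.exp(mu_at(times[k]) * dt)
        if latent > config.od_ceiling:
            latent *= config.dilution_factor
            dilutions.append(times[k])
        od[k] = latent
    if config.noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, config.noise_sd, od.size))
    return ODTrace(
        times=times,
        od=od,
        vial_id=config.vial_id,
        medium=config.medium,
        metadata={"dilution_times": dilutions, "phase_boundaries": boundaries},
    )


# ---------------------------------------------------------------------------
# landscape replicates


def simulate_landscape_replicates(
    truth: dict,
    n_reps: int = 10,
    cv: float = 0.1,
    seed: int | None = None,
    loci: tuple[str, ...] = DEFAULT_LOCI,
    condition: str = "M9/glucose",
) -> LandscapeMeasurement:
    """Lognormal replicate growth rates around a true genotype->mu map.

    Replicates have mean equal to the truth and coefficient of variation
    ``cv`` (the mean-correction term of the lognormal is applied).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    reps = {}
    for g, mu in truth.items():
        if mu <= 0:
            raise ValueError("growth rates must be positive")
        draws = mu * np.exp(rng.normal(-sigma**2 / 2, sigma, n_reps)) if cv > 0 else np.full(n_reps, float(mu))
        reps[g] = draws
    return LandscapeMeasurement(loci=loci, replicates=reps, condition=condition)


# ---------------------------------------------------------------------------
# assay plates


def simulate_assay_plate(
    true_concentrations,
    curve_shape: str = "linear",
    coefficients=(100.0, 0.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
    standard_concs=None,
) -> pd.DataFrame:
    """Plate readings for samples (and optionally standards) on a known curve.

    ``coefficients`` are polynomial coefficients, highest degree first
    (degree 1 for linear, 2 for quadratic); the curve must be monotone over
    the spanned concentration range.  Responses get additive Gaussian noise.
    """
    conc = np.asarray(true_concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    coefs = np.asarray(coefficients, dtype=float)
    degree = 1 if curve_shape == "linear" else 2
    if curve_shape not in ("linear", "quadratic"):
        raise ValueError("curve_shape must be 'linear' or 'quadratic'")
    if coefs.size != degree + 1:
        raise ValueError(f"{curve_shape} curve needs {degree + 1} coefficients")
    hi = float(conc.max()) if conc.size else 0.0
    if standard_concs is not None:
        std = np.asarray(standard_concs, dtype=float)
        if np.any(std < 0):
            raise ValueError("standard concentrations must be non-negative")
        hi = max(hi, float(std.max()))
    grid = np.linspace(0.0, hi, 257)
    dvals = np.polyval(np.polyder(coefs), grid)
    if np.any(dvals > 0) and np.any(dvals < 0):
        raise ValueError("curve is not monotone over the standard range")
    rng = np.random.default_rng(seed)

    rows = []
    if standard_concs is not None:
        for i, c in enumerate(np.asarray(standard_concs, dtype=float)):
            rows.append(
                {
                    "sample_id": f"std{i}",
                    "role": "standard",
                    "nominal_conc": c,
                    "response": float(np.polyval(coefs, c) + rng.normal(0.0, noise_sd)),
                }
            )
    for i, c in enumerate(conc):
        rows.append(
            {
                "sample_id": f"sample{i}",
                "role": "sample",
                "nominal_conc": c,
                "response": float(np.polyval(coefs, c) + rng.normal(0.0, noise_sd)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-condition presets


def reference_fitness_map() -> dict[Genotype, float]:
    """True growth rates (h^-1) of the 16 genotypes over the four loci.

    Values are reconstructed from the fold-changes reported for the evolved
    strain and its intermediates: the founder grows at 0.0094/h and the full
    quadruple mutant at 0.30/h (a 32-fold increase); the first mutation alone
    gives 4-fold; adding the second to it costs 4-fold (the cheater); the
    triple with the deletion grows at 0.10/h; the alternative triple on the
    "best" trajectory already matches the quadruple.  Exactly two steps
    (adding rpoS* or rpoC* to the gapA* single) significantly reduce fitness.
    """
    gapA, rpoS, d38, rpoC = range(4)

    def g(*on: int) -> Genotype:
        return tuple(1 if i in on else 0 for i in range(4))

    return {
        g(): 0.0094,
        g(gapA): 0.0375,
        g(rpoS): 0.0094,
        g(d38): 0.0097,
        g(rpoC): 0.0095,
        g(gapA, rpoS): 0.0094,
        g(gapA, d38): 0.110,
        g(gapA, rpoC): 0.0100,
        g(rpoS, d38): 0.0099,
        g(rpoS, rpoC): 0.0096,
        g(d38, rpoC): 0.0098,
        g(gapA, rpoS, d38): 0.100,
        g(gapA, rpoS, rpoC): 0.0098,
        g(gapA, d38, rpoC): 0.300,
        g(rpoS, d38, rpoC): 0.0099,
        g(gapA, rpoS, d38, rpoC): 0.300,
    }


def reference_accumulation_truth() -> dict[str, dict[str, float]]:
    """True B6 accumulation rates (pmol/(1e9 cfu h)) and growth rates.

    The first-step mutant accumulates B6 at 9 pmol/(1e9 cfu h); the
    slow-growing strains whose growth matches the founder serve as the
    parental proxy at about 3 pmol/(1e9 cfu h).
    """
    fm = reference_fitness_map()
    return {
        "gapA*": {"rate": 9.0, "mu": fm[(1, 0, 0, 0)]},
        "parental_proxy": {"rate": 3.0, "mu": fm[(0, 0, 1, 0)]},
    }


def default_lineage_config(
    seed: int | None = None,
    pop_size: int = 20_000,
    measurement_noise_sd: float = 0.0,
) -> SimulationConfig:
    """A clonal-interference scenario with nested lineages.

    Seven clones (each marked by one to two linked mutations) compete: a
    four-step nested chain emulating the winning lineage, and a two-step
    competing lineage that rises early and is later outcompeted.  Clones are
    seeded at low initial frequencies so their staggered sweeps are driven by
    selection, with drift on top.
    """
    fitness = {
        "": 0.30,
        "a1;a2": 0.36,
        "a1;a2;b1": 0.42,
        "a1;a2;b1;c1;c2": 0.50,
        "a1;a2;b1;c1;c2;d1": 0.58,
        "x1;x2": 0.41,
        "x1;x2;y1": 0.445,
    }
    init = {"": 0.99, "a1;a2": 0.01}
    intro = {
        "x1;x2": (18, 0.002),
        "a1;a2;b1": (22, 0.002),
        "x1;x2;y1": (40, 0.001),
        "a1;a2;b1;c1;c2": (70, 0.001),
        "a1;a2;b1;c1;c2;d1": (115, 0.001),
    }
    genes = {m: f"gene_{m[0]}" for m in "a1 a2 b1 c1 c2 d1 x1 x2 y1".split()}
    return SimulationConfig(
        fitness_map=fitness,
        initial_frequencies=init,
        introductions=intro,
        pop_size=pop_size,
        mutation_rate=0.0,
        gene_map=genes,
        measurement_noise_sd=measurement_noise_sd,
        seed=seed,
    )
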