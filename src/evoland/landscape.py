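"""Combinatorial fitness-landscape analysis over an L-locus genotype hypercube.

Every genotype is a presence/absence bit vector over L named loci (here the
four mutations gapA*, rpoS*, the 3.8 kb deletion and rpoC*), and its fitness
proxy is a set of replicate growth rates mu (h^-1).  The analysis classifies
every forward mutational step (Hamming-distance-1 edge adding one mutation)
as a significant increase, significant decrease or neither, using Welch's
unequal-variance t statistics corrected for multiple comparisons by the
Dunnett T3 procedure (studentized maximum modulus distribution evaluated at
each pair's Welch-Satterthwaite degrees of freedom).

On top of the classified edges the module computes:

* compact letter displays (insert-and-absorb) summarising statistical groups;
* accessibility: a step is accessible unless it significantly decreases
  fitness, and a genotype is accessible if at least one incoming forward step
  is accessible;
* exhaustive enumeration of the L! mutational orderings with per-step verdicts;
* the greedy "best" trajectory taking the largest mean increase at each step;
* multiplicative epistasis: the no-epistasis expectation for the full mutant
  is the product of single-mutant fold-changes, compared with the observed
  fold-change.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "LandscapeMeasurement",
    "EdgeClassification",
    "EpistasisSummary",
    "FitnessLandscapeAnalysis",
    "all_genotypes",
    "forward_edges",
    "welch_test",
    "smm_sf",
    "dunnett_t3_adjust",
    "sidak_adjust",
    "assign_statistical_groups",
    "classify_edges",
    "accessibility_summary",
    "enumerate_trajectories",
    "greedy_best_trajectory",
    "multiplicative_epistasis",
    "null_familywise_error_rate",
]

Genotype = tuple[int, ...]

DEFAULT_LOCI = ("gapA*", "rpoS*", "d3.8kb", "rpoC*")


# ---------------------------------------------------------------------------
# genotype combinatorics


def all_genotypes(n_loci: int) -> list[Genotype]:
    """All 2^L genotypes; bit i of the counting index flags locus i."""
    return [
        tuple((i >> b) & 1 for b in range(n_loci)) for i in range(2**n_loci)
    ]


def forward_edges(n_loci: int) -> list[tuple[Genotype, Genotype]]:
    """All L * 2^(L-1) mutation-adding edges of the hypercube."""
    edges = []
    for g in all_genotypes(n_loci):
        for i in range(n_loci):
            if g[i] == 0:
                child = tuple(1 if j == i else g[j] for j in range(n_loci))
                edges.append((g, child))
    return edges


def parse_genotype(label, loci: tuple[str, ...]) -> Genotype:
    """Parse '0101', 'gapA*;rpoC*' or an int/bool sequence into a bit tuple."""
    if isinstance(label, (tuple, list, np.ndarray)):
        g = tuple(int(b) for b in label)
        if len(g) != len(loci) or any(b not in (0, 1) for b in g):
            raise ValueError(f"bad genotype {label!r} for loci {loci}")
        return g
    s = str(label).strip()
    if set(s) <= {"0", "1"} and len(s) == len(loci):
        return tuple(int(c) for c in s)
    if s in ("", "founder", "parent", "-"):
        return (0,) * len(loci)
    names = [p.strip() for p in s.split(";") if p.strip()]
    unknown = [n for n in names if n not in loci]
    if unknown:
        raise ValueError(f"unknown loci {unknown}; expected subset of {loci}")
    return tuple(1 if loc in names else 0 for loc in loci)


def format_genotype(g: Genotype, loci: tuple[str, ...]) -> str:
    names = [loci[i] for i, b in enumerate(g) if b]
    return ";".join(names) if names else "founder"


# ---------------------------------------------------------------------------
# measurement container


@dataclass
class LandscapeMeasurement:
    """Replicate growth rates for every genotype of an L-locus landscape."""

    loci: tuple[str, ...]
    replicates: dict[Genotype, np.ndarray]
    condition: str = "M9/glucose"

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        self.replicates = {
            parse_genotype(g, self.loci): np.asarray(v, dtype=float)
            for g, v in self.replicates.items()
        }

    def validate(self) -> None:
        missing = [g for g in all_genotypes(len(self.loci)) if g not in self.replicates]
        if missing:
            raise ValueError(
                "missing genotypes: "
                + ", ".join(format_genotype(g, self.loci) for g in missing)
            )
        for g, reps in self.replicates.items():
            if reps.size < 2:
                raise ValueError(
                    f"genotype {format_genotype(g, self.loci)} has <2 replicates"
                )
            if np.any(reps <= 0):
                raise ValueError("growth rates must be positive")

    def mean(self, g: Genotype) -> float:
        return float(self.replicates[g].mean())

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, loci: tuple[str, ...] = DEFAULT_LOCI, condition: str = ""
    ) -> "LandscapeMeasurement":
        """Build from a long table with columns genotype, mu_h (replicate rows)."""
        reps: dict[Genotype, list[float]] = {}
        for _, row in df.iterrows():
            reps.setdefault(parse_genotype(row["genotype"], loci), []).append(
                float(row["mu_h"])
            )
        return cls(
            loci=loci,
            replicates={g: np.asarray(v) for g, v in reps.items()},
            condition=condition,
        )


# ---------------------------------------------------------------------------
# Welch statistics


def _welch_from_stats(m1, v1, n1, m2, v2, n2):
    """Vectorised Welch t and Welch-Satterthwaite df from summary statistics."""
    se2_1 = v1 / n1
    se2_2 = v2 / n2
    denom = np.sqrt(se2_1 + se2_2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
        df = (se2_1 + se2_2) ** 2 / (
            se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
        )
    return t, df


def welch_test(reps_a, reps_b) -> tuple[float, float, float]:
    """Welch's two-sample t test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom and
    a two-sided p value.  When both groups have zero variance and equal means
    the result is ``(0, n1+n2-2, 1)`` by convention.
    """
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf, float(a.size + b.size - 2), 0.0
    t, df = _welch_from_stats(a.mean(), v1, a.size, b.mean(), v2, b.size)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# studentized maximum modulus / Dunnett T3


def smm_sf(q, m, df, n_nodes: int = 513, chunk: int = 8192):
    """Survival function of the studentized maximum modulus distribution.

    ``P(max_i |T_i| > q)`` for ``m`` standard normal deviates studentized by a
    shared chi(df)/sqrt(df) factor, evaluated by Simpson quadrature over the
    studentizing density:

        P(SMM <= q) = int_0^inf [2*Phi(q u) - 1]^m f_U(u) du.

    Vectorised over ``q``/``df`` (broadcast together); ``m`` is scalar.  With
    ``m = 1`` this reduces exactly to the two-sided t tail probability.
    """
    scalar = np.ndim(q) == 0 and np.ndim(df) == 0
    q = np.atleast_1d(np.asarray(q, dtype=float))
    df = np.broadcast_to(np.asarray(df, dtype=float), q.shape).ravel()
    qf = q.ravel()
    if np.any(df <= 0):
        raise ValueError("df must be positive")
    out = np.empty(qf.shape)
    n = n_nodes if n_nodes % 2 == 1 else n_nodes + 1
    for a in range(0, qf.size, chunk):
        b = min(a + chunk, qf.size)
        qq = qf[a:b, None]
        dd = df[a:b, None]
        u_max = 1.0 + 15.0 / np.sqrt(dd)
        u = np.linspace(0.0, 1.0, n)[None, :] * u_max
        h = u_max / (n - 1)
        dens = stats.chi.pdf(u, dd, scale=1.0 / np.sqrt(dd))
        cdf_inner = np.clip(2.0 * stats.norm.cdf(np.abs(qq) * u) - 1.0, 0.0, 1.0)
        integrand = cdf_inner**m * dens
        w = np.ones(n)
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        cdf = (integrand @ w) * (h[:, 0] / 3.0)
        out[a:b] = 1.0 - np.clip(cdf, 0.0, 1.0)
    return float(out[0]) if scalar else out.reshape(q.shape)


def sidak_adjust(p_raw, m: int):
    """Sidak step-free adjustment 1 - (1-p)^m (fallback for T3)."""
    p = np.asarray(p_raw, dtype=float)
    return 1.0 - (1.0 - p) ** m


def dunnett_t3_adjust(t_values, dfs, m: int | None = None) -> np.ndarray:
    """Dunnett T3 adjusted p values for a family of Welch comparisons.

    Each comparison's |t| is referred to the studentized maximum modulus
    distribution with that pair's Welch df and the family size ``m``
    (default: the number of comparisons supplied).
    """
    t = np.abs(np.asarray(t_values, dtype=float))
    dfs = np.asarray(dfs, dtype=float)
    if m is None:
        m = t.size
    if m < 1:
        return np.empty(0)
    p_adj = smm_sf(t, m, dfs)
    return np.clip(p_adj, 0.0, 1.0)


# ---------------------------------------------------------------------------
# pairwise analysis and letters


@dataclass
class EdgeClassification:
    frm: Genotype
    to: Genotype
    fold_change: float  # mean(to) / mean(frm)
    t: float
    df: float
    p_raw: float
    p_adj: float
    klass: str  # significant_increase | significant_decrease | not_significant


def _pairwise_welch(measurement: LandscapeMeasurement):
    genotypes = all_genotypes(len(measurement.loci))
    pairs = list(itertools.combinations(range(len(genotypes)), 2))
    stats_by_pair = {}
    for i, j in pairs:
        a = measurement.replicates[genotypes[i]]
        b = measurement.replicates[genotypes[j]]
        t, df, p = welch_test(a, b)
        stats_by_pair[(i, j)] = (t, df, p)
    return genotypes, pairs, stats_by_pair


def classify_edges(
    measurement: LandscapeMeasurement,
    alpha: float = 0.05,
    family: str = "all-pairs",
) -> list[EdgeClassification]:
    """Classify every forward mutational step of the landscape.

    ``family`` selects the multiplicity family for the T3 adjustment:
    ``"all-pairs"`` (all k(k-1)/2 comparisons among the 2^L genotypes, the
    default, matching group-letter displays) or ``"edges"`` (the L*2^(L-1)
    forward steps only).
    """
    measurement.validate()
    L = len(measurement.loci)
    genotypes, pairs, stats_by_pair = _pairwise_welch(measurement)
    index = {g: i for i, g in enumerate(genotypes)}
    edge_list = forward_edges(L)
    edge_pairs = [tuple(sorted((index[a], index[b]))) for a, b in edge_list]
    if family == "all-pairs":
        fam_pairs = pairs
    elif family == "edges":
        fam_pairs = edge_pairs
    else:
        raise ValueError("family must be 'all-pairs' or 'edges'")
    m = len(fam_pairs)
    tvals = np.array([abs(stats_by_pair[p][0]) for p in fam_pairs])
    dfs = np.array([stats_by_pair[p][1] for p in fam_pairs])
    finite = np.isfinite(tvals)
    p_adj = np.ones_like(tvals)
    p_adj[finite] = dunnett_t3_adjust(tvals[finite], dfs[finite], m=m)
    p_adj[~finite] = 0.0
    adj_by_pair = dict(zip(fam_pairs, p_adj))

    out = []
    for (frm, to), pair in zip(edge_list, edge_pairs):
        t, df, p_raw = stats_by_pair[pair]
        pa = float(adj_by_pair[pair])
        diff = measurement.mean(to) - measurement.mean(frm)
        if pa < alpha:
            klass = "significant_increase" if diff > 0 else "significant_decrease"
        else:
            klass = "not_significant"
        out.append(
            EdgeClassification(
                frm=frm,
                to=to,
                fold_change=measurement.mean(to) / measurement.mean(frm),
                t=t if index[frm] < index[to] else -t,
                df=df,
                p_raw=p_raw,
                p_adj=pa,
                klass=klass,
            )
        )
    return out


def assign_statistical_groups(
    measurement: LandscapeMeasurement, alpha: float = 0.05
) -> dict[Genotype, str]:
    """Compact letter display over all genotypes (insert-and-absorb).

    Two genotypes share at least one letter iff their pairwise Dunnett-T3
    comparison is not significant at ``alpha``.
    """
    measurement.validate()
    genotypes, pairs, stats_by_pair = _pairwise_welch(measurement)
    m = len(pairs)
    tvals = np.array([abs(stats_by_pair[p][0]) for p in pairs])
    dfs = np.array([stats_by_pair[p][1] for p in pairs])
    finite = np.isfinite(tvals)
    p_adj = np.ones_like(tvals)
    p_adj[finite] = dunnett_t3_adjust(tvals[finite], dfs[finite], m=m)
    p_adj[~finite] = 0.0
    sig = {pair: bool(pa < alpha) for pair, pa in zip(pairs, p_adj)}
    letters = compact_letter_display(len(genotypes), sig)
    return {g: letters[i] for i, g in enumerate(genotypes)}


def compact_letter_display(
    n: int, significant: dict[tuple[int, int], bool]
) -> list[str]:
    """Insert-and-absorb compact letter display for ``n`` items.

    ``significant[(i, j)]`` (i < j) marks pairs that are significantly
    different.  Returns one letter string per item such that two items share
    a letter iff their pair is not significant.
    """
    columns: list[set[int]] = [set(range(n))]
    for (i, j), is_sig in sorted(significant.items()):
        if not is_sig:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            a, b = col - {i}, col - {j}
            for new in (a, b):
                if new and not any(new <= other for other in columns):
                    columns.append(new)
        # absorb: drop columns contained in another
        columns = [
            c for c in columns if not any(c < other for other in columns)
        ]
    # stable ordering: by smallest member
    columns.sort(key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = [""] * n
    for k, col in enumerate(columns):
        letter = alphabet[k] if k < len(alphabet) else f"<{k}>"
        for i in sorted(col):
            labels[i] += letter
    return labels


# ---------------------------------------------------------------------------
# accessibility and trajectories


def accessibility_summary(
    edges: list[EdgeClassification], mode: str = "not-decrease"
) -> tuple[int, int, set[Genotype]]:
    """Count accessible steps and genotypes.

    ``mode="not-decrease"`` (default): a step is accessible unless it is a
    significant decrease.  ``mode="increase"``: a step must be a significant
    increase.  A genotype is accessible if it has at least one accessible
    incoming forward step; the founder is accessible by definition.
    """
    if mode == "not-decrease":
        ok = lambda e: e.klass != "significant_decrease"
    elif mode == "increase":
        ok = lambda e: e.klass == "significant_increase"
    else:
        raise ValueError("mode must be 'not-decrease' or 'increase'")
    accessible_edges = [e for e in edges if ok(e)]
    L = len(edges[0].frm)
    reachable = {(0,) * L} | {e.to for e in accessible_edges}
    return len(accessible_edges), len(edges), reachable


def enumerate_trajectories(
    edges: list[EdgeClassification],
    loci: tuple[str, ...] | None = None,
    max_loci: int = 10,
) -> pd.DataFrame:
    """Annotate every mutational ordering (all L! of them) step by step.

    Each row holds one ordering, the class of each of its L steps, whether it
    is fully accessible (no significantly deleterious step) and how many
    deleterious steps it takes.
    """
    L = len(edges[0].frm)
    if L > max_loci:
        raise ValueError(
            f"{L}! orderings exceed the enumeration guard ({max_loci} loci); "
            "sample orderings instead"
        )
    by_edge = {(e.frm, e.to): e for e in edges}
    loci = loci or tuple(f"locus{i}" for i in range(L))
    rows = []
    for order in itertools.permutations(range(L)):
        g = (0,) * L
        classes = []
        for locus in order:
            child = tuple(1 if j == locus else g[j] for j in range(L))
            classes.append(by_edge[(g, child)].klass)
            g = child
        n_dec = sum(c == "significant_decrease" for c in classes)
        rows.append(
            {
                "ordering": " -> ".join(loci[i] for i in order),
                **{f"step{k+1}_class": c for k, c in enumerate(classes)},
                "n_decrease_steps": n_dec,
                "fully_accessible": n_dec == 0,
            }
        )
    return pd.DataFrame(rows)


def greedy_best_trajectory(measurement: LandscapeMeasurement) -> list[int]:
    """Mutation order taking the largest mean growth-rate increase each step.

    Ties are broken by locus order with a warning.  Returns locus indices in
    the order acquired.
    """
    measurement.validate()
    L = len(measurement.loci)
    g = (0,) * L
    order: list[int] = []
    while len(order) < L:
        options = []
        for i in range(L):
            if g[i] == 0:
                child = tuple(1 if j == i else g[j] for j in range(L))
                options.append((measurement.mean(child), -i))
        best = max(options)
        if sum(1 for o in options if o[0] == best[0]) > 1:
            warnings.warn(
                f"tie among next steps from {format_genotype(g, measurement.loci)}; "
                "broken by locus order"
            )
            best = max(o for o in options if o[0] == best[0])
        locus = -best[1]
        order.append(locus)
        g = tuple(1 if j == locus else g[j] for j in range(L))
    return order


# ---------------------------------------------------------------------------
# epistasis


@dataclass
class EpistasisSummary:
    expected_fold: float  # product of single-mutant fold-changes
    observed_fold: float  # full mutant / founder
    ratio: float  # observed / expected
    single_mutant_folds: dict[str, float] = field(default_factory=dict)
    max_single_fold: float = float("nan")  # "others neutral" reading
    ratio_ci95: tuple[float, float] | None = None


def multiplicative_epistasis(
    measurement: LandscapeMeasurement,
    n_boot: int = 2000,
    random_state: int | None = 0,
) -> EpistasisSummary:
    """Observed vs expected (multiplicative) fold-change of the full mutant.

    The no-epistasis expectation multiplies the fold-changes of the single
    mutants relative to the founder; the observed fold is the full mutant's
    mean growth rate over the founder's.  ``max_single_fold`` reports the
    alternative reading in which only the largest single effect matters and
    the rest are treated as neutral.  The ratio's CI is a replicate bootstrap.
    """
    measurement.validate()
    L = len(measurement.loci)
    founder = (0,) * L
    full = (1,) * L
    mu0 = measurement.mean(founder)
    if mu0 <= 0:
        raise ValueError("founder mean growth rate must be positive")
    singles = {}
    for i in range(L):
        g = tuple(1 if j == i else 0 for j in range(L))
        singles[measurement.loci[i]] = measurement.mean(g) / mu0
    expected = float(np.prod(list(singles.values())))
    observed = measurement.mean(full) / mu0
    rng = np.random.default_rng(random_state)

    def boot_ratio() -> float:
        def bmean(g):
            reps = measurement.replicates[g]
            return rng.choice(reps, size=reps.size).mean()

        m0 = bmean(founder)
        exp = np.prod(
            [
                bmean(tuple(1 if j == i else 0 for j in range(L))) / m0
                for i in range(L)
            ]
        )
        return (bmean(full) / m0) / exp

    boots = np.array([boot_ratio() for _ in range(n_boot)])
    return EpistasisSummary(
        expected_fold=expected,
        observed_fold=observed,
        ratio=observed / expected,
        single_mutant_folds=singles,
        max_single_fold=float(max(singles.values())),
        ratio_ci95=(float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))),
    )


# ---------------------------------------------------------------------------
# null calibration


def null_familywise_error_rate(
    n_groups: int = 16,
    n_reps: int = 8,
    n_families: int = 2000,
    alpha: float = 0.05,
    random_state: int | None = 0,
) -> float:
    """Familywise type-I error of the all-pairs Welch+T3 pipeline under the null.

    Simulates ``n_families`` landscapes whose groups are all identical
    (standard normal shifted to a positive mean) and returns the fraction of
    families with at least one adjusted p below ``alpha``.
    """
    rng = np.random.default_rng(random_state)
    k = n_groups
    pairs = np.array(list(itertools.combinations(range(k), 2)))
    m = len(pairs)
    data = rng.standard_normal((n_families, k, n_reps))
    means = data.mean(axis=2)
    vars_ = data.var(axis=2, ddof=1)
    i, j = pairs[:, 0], pairs[:, 1]
    t, df = _welch_from_stats(
        means[:, i], vars_[:, i], n_reps, means[:, j], vars_[:, j], n_reps
    )
    p_adj = smm_sf(np.abs(t), m, df)
    any_sig = (p_adj < alpha).any(axis=1)
    return float(any_sig.mean())


# ---------------------------------------------------------------------------
# estimator facade


class FitnessLandscapeAnalysis(BaseEstimator):
    """Full statistical analysis of an L-locus fitness landscape.

    Parameters
    ----------
    alpha : significance level for adjusted p values.
    family : multiplicity family for edge classification
        ("all-pairs" or "edges").
    accessible_mode : "not-decrease" (dashed-step reading) or "increase".
    n_boot, random_state : bootstrap settings.

    Attributes (after :meth:`fit`)
    ------------------------------
    edges_ : list of :class:`EdgeClassification`
    groups_ : ``DataFrame`` with genotype, mean mu, 95% CI and letters
    letters_ : mapping genotype -> letter string
    accessibility_ : (n_accessible, n_total, reachable set)
    trajectories_ : ``DataFrame`` of all orderings
    greedy_path_ : locus indices of the greedy best trajectory
    epistasis_ : :class:`EpistasisSummary`
    """

    def __init__(
        self,
        alpha: float = 0.05,
        family: str = "all-pairs",
        accessible_mode: str = "not-decrease",
        n_boot: int = 2000,
        random_state: int | None = 0,
    ) -> None:
        self.alpha = alpha
        self.family = family
        self.accessible_mode = accessible_mode
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, measurement, y=None) -> "FitnessLandscapeAnalysis":
        if isinstance(measurement, pd.DataFrame):
            measurement = LandscapeMeasurement.from_frame(measurement)
        measurement.validate()
        self.measurement_ = measurement
        self.edges_ = classify_edges(measurement, alpha=self.alpha, family=self.family)
        self.letters_ = assign_statistical_groups(measurement, alpha=self.alpha)
        rows = []
        for g in all_genotypes(len(measurement.loci)):
            reps = measurement.replicates[g]
            sem = reps.std(ddof=1) / math.sqrt(reps.size)
            half = stats.t.ppf(0.975, reps.size - 1) * sem
            rows.append(
                {
                    "genotype": format_genotype(g, measurement.loci),
                    "mean_mu": reps.mean(),
                    "ci95_lo": reps.mean() - half,
                    "ci95_hi": reps.mean() + half,
                    "n": reps.size,
                    "letters": self.letters_[g],
                }
            )
        self.groups_ = pd.DataFrame(rows)
        self.accessibility_ = accessibility_summary(
            self.edges_, mode=self.accessible_mode
        )
        self.trajectories_ = enumerate_trajectories(self.edges_, measurement.loci)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.greedy_path_ = greedy_best_trajectory(measurement)
        self.epistasis_ = multiplicative_epistasis(
            measurement, n_boot=self.n_boot, random_state=self.random_state
        )
        return self

    def edges_frame(self) -> pd.DataFrame:
        loci = self.measurement_.loci
        return pd.DataFrame(
            [
                {
                    "from": format_genotype(e.frm, loci),
                    "to": format_genotype(e.to, loci),
                    "fold_change": e.fold_change,
                    "t": e.t,
                    "df": e.df,
                    "p_raw": e.p_raw,
                    "p_adj": e.p_adj,
                    "class": e.klass,
                }
                for e in self.edges_
            ]
        )
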