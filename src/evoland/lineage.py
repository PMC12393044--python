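"""Clone lineage inference from mutation-frequency time series.

Mixed-population sequencing of an evolving microbial culture yields, for every
mutation, its frequency in the population at each sampled generation.  Mutations
that arose in the same clone rise and fall together, so correlated frequency
trajectories can be clustered into clones, and the containment structure of
clone abundances (a clone born inside another can never be more abundant than
its host) yields a nested lineage forest — the structure drawn by a Muller plot.

The module implements the four stages of that reconstruction:

1. :func:`filter_trajectories` — discard noise-level trajectories using the
   detection rules (consecutive observation, minimum frequency, gene rescue);
2. :func:`cluster_into_clones` — average-linkage clustering on correlation
   distance, with a maximum-frequency-gap guard;
3. :func:`infer_nesting` — containment-based parent assignment with a
   sibling-sum consistency check;
4. :func:`muller_matrix` — per-clone band widths over interpolated time.

:func:`detect_amplification` additionally scans a read-coverage track for
large amplified regions (windows whose depth exceeds a multiple of the
genome-wide median).

A sklearn-style estimator, :class:`CloneLineageInference`, chains stages 1-4.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "Clone",
    "LineageForest",
    "CloneLineageInference",
    "generation_columns",
    "filter_trajectories",
    "cluster_into_clones",
    "infer_nesting",
    "muller_matrix",
    "detect_amplification",
]

#: columns of a frequency table that are not generation columns
ID_COLUMNS = ("mutation_id", "gene", "position", "description")


# ---------------------------------------------------------------------------
# data containers


@dataclass
class Clone:
    """One clone: a set of co-occurring mutations with a shared trajectory."""

    clone_id: str
    mutations: tuple[str, ...]
    parent: str | None  # None = root (child of the ancestral background)
    abundance: np.ndarray  # fraction of the population per sampled generation

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)


@dataclass
class LineageForest:
    """Nested clone hierarchy with per-generation abundances."""

    generations: np.ndarray
    clones: dict[str, Clone] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)

    def roots(self) -> list[str]:
        return [c for c, cl in self.clones.items() if cl.parent is None]

    def children(self, clone_id: str | None) -> list[str]:
        return [c for c, cl in self.clones.items() if cl.parent == clone_id]

    def ancestor_residual(self) -> np.ndarray:
        """Fraction of the population carrying none of the tracked clones."""
        total = np.zeros_like(self.generations, dtype=float)
        for cid in self.roots():
            total += self.clones[cid].abundance
        return np.clip(1.0 - total, 0.0, 1.0)

    def validate(self, epsilon: float = 0.05) -> None:
        """Check containment and sibling-sum invariants at tolerance epsilon."""
        for cid, clone in self.clones.items():
            if clone.parent is not None:
                parent = self.clones[clone.parent].abundance
                if np.any(clone.abundance > parent + epsilon):
                    raise ValueError(
                        f"clone {cid!r} exceeds its parent {clone.parent!r}"
                    )
        for pid in [None, *self.clones]:
            kids = self.children(pid)
            if not kids:
                continue
            ceiling = (
                np.ones_like(self.generations, dtype=float)
                if pid is None
                else self.clones[pid].abundance
            )
            sibling_sum = np.sum([self.clones[k].abundance for k in kids], axis=0)
            if np.any(sibling_sum > ceiling + epsilon):
                raise ValueError(
                    f"children of {pid!r} sum above their parent: {kids}"
                )

    def to_dict(self) -> dict:
        return {
            "generations": self.generations.tolist(),
            "clones": {
                cid: {
                    "mutations": list(c.mutations),
                    "parent": c.parent,
                    "abundance": c.abundance.tolist(),
                }
                for cid, c in self.clones.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LineageForest":
        forest = cls(generations=np.asarray(payload["generations"], dtype=float))
        for cid, rec in payload["clones"].items():
            forest.clones[cid] = Clone(
                clone_id=cid,
                mutations=tuple(rec["mutations"]),
                parent=rec["parent"],
                abundance=np.asarray(rec["abundance"], dtype=float),
            )
        return forest


# ---------------------------------------------------------------------------
# frequency-table helpers


def generation_columns(table: pd.DataFrame) -> list:
    """Columns of *table* holding per-generation frequencies, in time order."""
    cols = []
    for col in table.columns:
        if str(col) in ID_COLUMNS:
            continue
        try:
            float(col)
        except (TypeError, ValueError):
            continue
        cols.append(col)
    gens = [float(c) for c in cols]
    if gens != sorted(gens):
        raise ValueError("generation columns must be in increasing order")
    return cols


def _frequency_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list]:
    cols = generation_columns(table)
    if not cols:
        raise ValueError("table has no generation columns")
    freqs = table[cols].to_numpy(dtype=float)
    if np.any(freqs < 0):
        raise ValueError("negative mutation frequencies")
    if np.any(freqs > 1):
        warnings.warn("frequencies above 1 clipped to 1 (sequencing noise)")
        freqs = np.minimum(freqs, 1.0)
    return freqs, np.array([float(c) for c in cols]), cols


# ---------------------------------------------------------------------------
# stage 1: trajectory filtering


def filter_trajectories(
    table: pd.DataFrame,
    min_consecutive: int = 2,
    min_freq: float = 0.10,
    rescue_mutated_genes: bool = True,
    predicate: str = "and",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the trajectory detection rules to a mutation-frequency table.

    A mutation is retained directly if it was observed (frequency > 0) at
    ``min_consecutive`` or more consecutive timepoints and its maximum
    frequency exceeds ``min_freq`` (``predicate="and"``, the default), or if
    either condition holds (``predicate="or"``).  A mutation that fails the
    direct rule is rescued when another mutation in the same gene was retained
    directly (``rescue_mutated_genes``).

    Returns the filtered table and an audit table recording, for every row,
    whether it was kept and by which rule.
    """
    if predicate not in ("and", "or"):
        raise ValueError("predicate must be 'and' or 'or'")
    freqs, _, _ = _frequency_matrix(table)

    observed = freqs > 0
    # longest run of consecutive observations per row
    run_len = np.zeros(len(table), dtype=int)
    current = np.zeros(len(table), dtype=int)
    for j in range(observed.shape[1]):
        current = np.where(observed[:, j], current + 1, 0)
        run_len = np.maximum(run_len, current)
    max_freq = freqs.max(axis=1)

    consec_ok = run_len >= min_consecutive
    freq_ok = max_freq > min_freq
    direct = (consec_ok & freq_ok) if predicate == "and" else (consec_ok | freq_ok)

    genes = table["gene"].astype(str) if "gene" in table.columns else pd.Series(
        [""] * len(table), index=table.index
    )
    retained_genes = set(genes[direct]) - {""}
    rescued = (
        genes.isin(retained_genes).to_numpy() & ~direct
        if rescue_mutated_genes
        else np.zeros(len(table), dtype=bool)
    )
    kept = direct | rescued

    rule = np.where(
        direct,
        "direct",
        np.where(rescued, "gene-rescue", "dropped"),
    )
    audit = pd.DataFrame(
        {
            "mutation_id": table["mutation_id"]
            if "mutation_id" in table.columns
            else table.index,
            "kept": kept,
            "rule": rule,
            "max_frequency": max_freq,
            "longest_run": run_len,
        }
    )
    return table.loc[kept].reset_index(drop=True), audit


# ---------------------------------------------------------------------------
# stage 2: clustering into clones


def _trajectory_distances(freqs: np.ndarray, max_gap: float) -> np.ndarray:
    """Pairwise distance 1 - Pearson r, guarded by a max-frequency-gap veto.

    Trajectories that are correlated but vertically offset by more than
    ``max_gap`` belong to different (nested) clones, so their distance is
    pushed beyond any correlation distance.  Zero-variance trajectories have
    undefined correlation and are kept as singletons (distance 3).
    """
    n = freqs.shape[0]
    sd = freqs.std(axis=1)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            gap = np.max(np.abs(freqs[i] - freqs[j]))
            if sd[i] == 0 or sd[j] == 0:
                d = 0.0 if np.allclose(freqs[i], freqs[j]) else 3.0
            else:
                r = np.corrcoef(freqs[i], freqs[j])[0, 1]
                d = 1.0 - r
            if gap > max_gap:
                d = max(d, 2.0 + gap)
            dist[i, j] = dist[j, i] = d
    return dist


def cluster_into_clones(
    table: pd.DataFrame,
    linkage_threshold: float = 0.15,
    max_gap: float = 0.15,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Group mutations whose frequency trajectories co-move into clones.

    Returns ``(labels, abundances)`` where ``labels[i]`` is the clone id of
    row ``i`` and ``abundances`` maps clone id to its mean member trajectory.
    """
    freqs, _, _ = _frequency_matrix(table)
    n = len(table)
    if n == 0:
        raise ValueError("no retained mutations to cluster")
    if np.any(freqs.std(axis=1) == 0):
        warnings.warn("constant (e.g. all-zero) trajectory assigned to a singleton clone")
    if n == 1:
        labels = np.array(["C1"])
    else:
        dist = _trajectory_distances(freqs, max_gap)
        z = linkage(squareform(dist, checks=False), method="average")
        flat = fcluster(z, t=linkage_threshold, criterion="distance")
        labels = np.array([f"C{k}" for k in flat])
    abundances = {
        cid: freqs[labels == cid].mean(axis=0) for cid in dict.fromkeys(labels)
    }
    return labels, abundances


# ---------------------------------------------------------------------------
# stage 3: nesting inference


def _emergence_index(abundance: np.ndarray, floor: float) -> float:
    idx = np.nonzero(abundance > floor)[0]
    return float(idx[0]) if idx.size else np.inf


def infer_nesting(
    abundances: dict[str, np.ndarray],
    generations,
    members: dict[str, tuple[str, ...]] | None = None,
    epsilon: float = 0.05,
    detection_floor: float = 0.01,
) -> LineageForest:
    """Build a lineage forest by containment of clone abundance trajectories.

    Clone B nests inside clone A iff B never exceeds A by more than
    ``epsilon``; when containment is mutual (near-identical trajectories) the
    earlier-emerging, larger clone takes precedence as host.  Among eligible
    hosts the smallest enclosing clone is chosen.  After parent assignment, sibling sums
    are checked against each parent (children of the virtual root against 1);
    a violating child is re-parented to the next-smallest enclosing clone, and
    an unresolvable violation raises ``ValueError`` naming the clones.
    """
    generations = np.asarray(generations, dtype=float)
    ids = list(abundances)
    ab = {c: np.asarray(abundances[c], dtype=float) for c in ids}
    emergence = {c: _emergence_index(ab[c], detection_floor) for c in ids}
    total = {c: float(ab[c].sum()) for c in ids}
    # fixed precedence prevents containment cycles between near-identical clones
    order = sorted(ids, key=lambda c: (-total[c], emergence[c], c))
    rank = {c: i for i, c in enumerate(order)}

    def encloses(a: str, b: str) -> bool:
        return bool(np.all(ab[b] <= ab[a] + epsilon))

    # candidate parents for each clone, nearest (smallest) enclosing first;
    # the virtual root is always eligible as a fallback
    candidates: dict[str, list[str | None]] = {}
    for b in ids:
        cands = [a for a in ids if rank[a] < rank[b] and encloses(a, b)]
        cands.sort(key=lambda a: (total[a], rank[a]))
        candidates[b] = [*cands, None]

    def sibling_ok(parent: dict[str, str | None]) -> bool:
        for pid in [None, *ids]:
            kids = [c for c in ids if parent[c] == pid]
            if not kids:
                continue
            ceiling = np.ones_like(generations) if pid is None else ab[pid]
            if np.any(np.sum([ab[k] for k in kids], axis=0) > ceiling + epsilon):
                return False
        return True

    # bounded exhaustive search over candidate assignments, preferring the
    # most-nested forest (nearest enclosing parents tried first)
    n_combos = int(np.prod([len(candidates[b]) for b in ids]))
    if n_combos > 500_000:
        raise ValueError(
            f"nesting search space too large ({n_combos} assignments); "
            "reduce the number of clones or loosen epsilon"
        )
    parent: dict[str, str | None] | None = None
    clone_order = sorted(ids, key=lambda c: rank[c])
    for combo in itertools.product(*(candidates[b] for b in clone_order)):
        trial = dict(zip(clone_order, combo))
        if sibling_ok(trial):
            parent = trial
            break
    if parent is None:
        raise ValueError(
            f"no consistent lineage forest at epsilon={epsilon}: "
            f"conflicting clones {sorted(ids)}"
        )

    forest = LineageForest(generations=generations)
    for c in ids:
        forest.clones[c] = Clone(
            clone_id=c,
            mutations=tuple(members.get(c, ())) if members else (),
            parent=parent[c],
            abundance=ab[c],
        )
    forest.validate(epsilon=epsilon)
    return forest


# ---------------------------------------------------------------------------
# stage 4: Muller matrix


def muller_matrix(
    forest: LineageForest, interpolation_points: int = 200
) -> pd.DataFrame:
    """Band widths of the Muller diagram over interpolated time.

    Rows are bands in plotting order (ancestor first, then clones depth-first
    by emergence); columns are ``interpolation_points`` timepoints linearly
    spaced from generation 0 (all-ancestor state) to the last sampled
    generation.  Each clone's own band width is its abundance minus the summed
    abundance of its children, clipped at 0; columns are normalised to sum to 1.
    """
    forest.validate()
    gens = forest.generations
    # prepend the all-ancestor state at generation 0
    if gens.size == 0:
        raise ValueError("forest has no sampled generations")
    tgrid = np.linspace(0.0, gens[-1], interpolation_points)

    def interp(abund: np.ndarray) -> np.ndarray:
        if gens[0] > 0:
            xs = np.concatenate([[0.0], gens])
            ys = np.concatenate([[0.0], abund])
        else:
            xs, ys = gens, abund
        return np.interp(tgrid, xs, ys)

    clone_ab = {cid: interp(c.abundance) for cid, c in forest.clones.items()}

    order: list[str] = []

    def visit(cid: str) -> None:
        order.append(cid)
        kids = sorted(
            forest.children(cid),
            key=lambda k: (_emergence_index(clone_ab[k], 0.0), k),
        )
        for k in kids:
            visit(k)

    for root in sorted(
        forest.roots(), key=lambda k: (_emergence_index(clone_ab[k], 0.0), k)
    ):
        visit(root)

    rows = {}
    root_sum = np.sum([clone_ab[r] for r in forest.roots()], axis=0) if forest.roots() else 0.0
    rows["ancestor"] = np.clip(1.0 - root_sum, 0.0, None)
    for cid in order:
        kid_sum = (
            np.sum([clone_ab[k] for k in forest.children(cid)], axis=0)
            if forest.children(cid)
            else 0.0
        )
        rows[cid] = np.clip(clone_ab[cid] - kid_sum, 0.0, None)

    mat = pd.DataFrame(rows, index=tgrid).T
    colsum = mat.sum(axis=0).to_numpy()
    if np.any(colsum <= 0):
        raise ValueError("empty Muller column")
    mat = mat / colsum
    return mat


# ---------------------------------------------------------------------------
# coverage amplification


def detect_amplification(
    track: pd.DataFrame,
    ratio_threshold: float = 1.5,
    min_length_bp: int = 10_000,
    merge_gap_bp: int = 5_000,
) -> pd.DataFrame:
    """Find amplified genomic intervals in a windowed read-coverage track.

    *track* has bedGraph-like columns ``chrom, start, end, depth`` with
    non-overlapping, sorted windows (0-based half-open).  The baseline is the
    genome-wide median depth; runs of windows with ``depth / baseline >=
    ratio_threshold`` are merged across gaps of at most ``merge_gap_bp`` and
    reported if their span is at least ``min_length_bp``, with the copy ratio
    estimated as the median in-interval depth over the baseline.
    """
    required = {"chrom", "start", "end", "depth"}
    if not required.issubset(track.columns):
        raise ValueError(f"coverage track needs columns {sorted(required)}")
    if len(track) < 20:
        raise ValueError("need at least 20 windows to estimate a baseline")
    baseline = float(track["depth"].median())
    if baseline <= 0:
        raise ValueError("zero median depth: cannot normalise coverage")

    out = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        if np.any(sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]):
            raise ValueError("coverage windows overlap")
        hot = sub[sub["depth"] / baseline >= ratio_threshold]
        if hot.empty:
            continue
        run_start = run_end = None
        depths: list[float] = []

        def flush() -> None:
            if run_start is None:
                return
            if run_end - run_start >= min_length_bp:
                out.append(
                    {
                        "chrom": chrom,
                        "start": int(run_start),
                        "end": int(run_end),
                        "copy_ratio": float(np.median(depths)) / baseline,
                    }
                )

        for _, win in hot.iterrows():
            if run_start is not None and win["start"] - run_end <= merge_gap_bp:
                run_end = win["end"]
                depths.append(win["depth"])
            else:
                flush()
                run_start, run_end = win["start"], win["end"]
                depths = [win["depth"]]
        flush()
    return pd.DataFrame(out, columns=["chrom", "start", "end", "copy_ratio"])


# ---------------------------------------------------------------------------
# estimator facade


class CloneLineageInference(ClusterMixin, BaseEstimator):
    """Full lineage reconstruction from a mutation-frequency table.

    Chains trajectory filtering, clone clustering, nesting inference and
    Muller-matrix export.  Parameters mirror the stage functions.

    Attributes (after :meth:`fit`)
    ------------------------------
    labels_ : ndarray of clone ids, one per retained mutation row
    filtered_ : the filtered frequency table
    audit_ : per-mutation audit of the filtering rules
    forest_ : :class:`LineageForest`
    muller_ : Muller band matrix (``DataFrame``)
    """

    def __init__(
        self,
        min_consecutive: int = 2,
        min_freq: float = 0.10,
        rescue_mutated_genes: bool = True,
        predicate: str = "and",
        linkage_threshold: float = 0.15,
        max_gap: float = 0.15,
        epsilon: float = 0.05,
        detection_floor: float = 0.01,
        interpolation_points: int = 200,
    ) -> None:
        self.min_consecutive = min_consecutive
        self.min_freq = min_freq
        self.rescue_mutated_genes = rescue_mutated_genes
        self.predicate = predicate
        self.linkage_threshold = linkage_threshold
        self.max_gap = max_gap
        self.epsilon = epsilon
        self.detection_floor = detection_floor
        self.interpolation_points = interpolation_points

    def fit(self, table: pd.DataFrame, y=None) -> "CloneLineageInference":
        filtered, audit = filter_trajectories(
            table,
            min_consecutive=self.min_consecutive,
            min_freq=self.min_freq,
            rescue_mutated_genes=self.rescue_mutated_genes,
            predicate=self.predicate,
        )
        labels, abundances = cluster_into_clones(
            filtered,
            linkage_threshold=self.linkage_threshold,
            max_gap=self.max_gap,
        )
        members = {
            cid: tuple(
                filtered.loc[labels == cid, "mutation_id"].astype(str)
                if "mutation_id" in filtered.columns
                else map(str, np.nonzero(labels == cid)[0])
            )
            for cid in dict.fromkeys(labels)
        }
        gens = [float(c) for c in generation_columns(filtered)]
        forest = infer_nesting(
            abundances,
            gens,
            members=members,
            epsilon=self.epsilon,
            detection_floor=self.detection_floor,
        )
        self.filtered_ = filtered
        self.audit_ = audit
        self.labels_ = labels
        self.forest_ = forest
        self.muller_ = muller_matrix(forest, self.interpolation_points)
        return self

    def fit_predict(self, table: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(table).labels_
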