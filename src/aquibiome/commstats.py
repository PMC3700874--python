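"""Community comparison statistics: Bray-Curtis, ANOSIM, SIMPER, NMDS.

These are implemented directly from their definitions rather than wrapped
from another package: Bray-Curtis dissimilarity between count/abundance
vectors, the rank-based ANOSIM permutation test with its customary
interpretation bands (R < 0.25 indistinct, 0.25-0.75 overlapping, > 0.75
distinct), SIMPER decomposition of average between-group dissimilarity
into per-OTU contributions, and nonmetric multidimensional scaling
minimizing Kruskal stress-1 by alternating isotonic regression and
Guttman (SMACOF) configuration updates.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .otu import OtuTable

__all__ = [
    "DistanceMatrix",
    "bray_curtis",
    "AnosimBand",
    "AnosimResult",
    "anosim",
    "SimperResult",
    "simper",
    "NmdsResult",
    "nmds",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """A labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("labels do not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def bray_curtis(table: OtuTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = 1 − 2·Σ min(x, y) / (Σx + Σy).

    Computed between every pair of sample rows of the count (or relative
    abundance) table.  All-zero samples are rejected by name.
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = counts.index[totals == 0][0]
        raise ValueError(f"all-zero sample {bad!r}")
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.minimum(x[i], x[j]).sum()
            d[i, j] = d[j, i] = 1.0 - 2.0 * shared / (totals[i] + totals[j])
    return DistanceMatrix(tuple(str(s) for s in counts.index), d)


class AnosimBand(str, enum.Enum):
    """Customary interpretation of the ANOSIM R statistic."""

    INDISTINCT = "indistinct"  # R < 0.25
    OVERLAPPING = "overlapping"  # 0.25 ≤ R ≤ 0.75
    DISTINCT = "distinct"  # R > 0.75

    @classmethod
    def from_r(cls, r: float) -> "AnosimBand":
        if r > 0.75:
            return cls.DISTINCT
        if r >= 0.25:
            return cls.OVERLAPPING
        return cls.INDISTINCT


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_perms: int
    band: AnosimBand
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.R <= 1.0 + 1e-9):
            raise ValueError(f"R {self.R} outside [-1, 1]")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p {self.p} outside (0, 1]")


def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray, m: int) -> float:
    r_within = ranks[within_mask].mean()
    r_between = ranks[~within_mask].mean()
    return (r_between - r_within) / (m / 2.0)


def _within_mask(labels: np.ndarray, pair_idx: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    i, j = pair_idx
    return labels[i] == labels[j]


def _multiset_permutations(items: Sequence[int]):
    """Distinct permutations of a label multiset (lazy)."""
    counts = {}
    for it in items:
        counts[it] = counts.get(it, 0) + 1
    keys = sorted(counts)

    def rec(remaining: int, current: list[int]):
        if remaining == 0:
            yield tuple(current)
            return
        for k in keys:
            if counts[k] > 0:
                counts[k] -= 1
                current.append(k)
                yield from rec(remaining - 1, current)
                current.pop()
                counts[k] += 1

    yield from rec(len(items), [])


def _n_multiset_permutations(items: Sequence[int]) -> int:
    counts: dict[int, int] = {}
    for it in items:
        counts[it] = counts.get(it, 0) + 1
    total = math.factorial(len(items))
    for c in counts.values():
        total //= math.factorial(c)
    return total


def anosim(
    dm: DistanceMatrix,
    groups: Mapping[str, str] | Sequence[str],
    n_perms: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """ANOSIM: rank-based contrast of between- vs within-group distances.

    All off-diagonal distances are ranked (mid-ranks for ties) and
    R = (r̄_between − r̄_within)/(M/2) with M = n(n−1)/2.  Significance is
    by label permutation: exhaustive enumeration of the distinct label
    assignments when there are at most ``n_perms`` of them, otherwise
    ``n_perms`` random permutations with the +1 correction
    p = (1 + #{R_perm ≥ R_obs})/(1 + n_perms).
    """
    if isinstance(groups, Mapping):
        labels_str = [groups[l] for l in dm.labels]
    else:
        if len(groups) != dm.n:
            raise ValueError("group vector length mismatch")
        labels_str = list(groups)
    uniq = sorted(set(labels_str))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    sizes = {g: labels_str.count(g) for g in uniq}
    singletons = [g for g, c in sizes.items() if c < 2]
    if singletons:
        raise ValueError(f"singleton group(s): {singletons}")
    if n_perms < 99:
        raise ValueError("n_perms must be ≥ 99")

    labels = np.array([uniq.index(g) for g in labels_str])
    n = dm.n
    iu = np.triu_indices(n, k=1)
    dist = dm.values[iu]
    ranks = rankdata(dist)  # mid-ranks for ties
    m = n * (n - 1) // 2

    observed = _anosim_r(ranks, _within_mask(labels, iu), m)

    n_total = _n_multiset_permutations(labels.tolist())
    if n_total <= n_perms:
        count = 0
        for perm in _multiset_permutations(labels.tolist()):
            r = _anosim_r(ranks, _within_mask(np.array(perm), iu), m)
            if r >= observed - 1e-12:
                count += 1
        p = count / n_total
        n_used = n_total
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        work = labels.copy()
        for _ in range(n_perms):
            rng.shuffle(work)
            r = _anosim_r(ranks, _within_mask(work, iu), m)
            if r >= observed - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perms)
        n_used = n_perms
        exhaustive = False
    return AnosimResult(observed, p, n_used, AnosimBand.from_r(observed), exhaustive)


@dataclass(frozen=True)
class SimperResult:
    """Per-OTU decomposition of average between-group Bray-Curtis.

    ``table`` columns: ``contribution`` (average over cross-group sample
    pairs), ``percent``, ``cumulative_percent``, ``rank`` (1 = most
    responsible).  ``total_dissimilarity`` is the average Bray-Curtis
    dissimilarity between the groups; if it is zero the decomposition is
    degenerate and percentages are undefined (NaN).
    """

    table: pd.DataFrame
    total_dissimilarity: float
    degenerate: bool = False


def simper(
    table: OtuTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    normalize: bool = True,
) -> SimperResult:
    """SIMPER: rank OTUs by their contribution to between-group dissimilarity.

    Samples are first converted to relative abundance (clone libraries
    differ in size); pass ``normalize=False`` to decompose raw-count
    Bray-Curtis instead.  For every cross-group pair (i, j), OTU k
    contributes δ_k = |x_ik − x_jk| / Σ_m (x_im + x_jm); contributions are
    averaged over all pairs, and per pair they sum exactly to the
    Bray-Curtis dissimilarity d(i, j) of the (normalized or raw) rows.
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    rel = table.relative_abundance() if normalize else table.counts.astype(float)
    a = rel.loc[list(group_a)].to_numpy()
    b = rel.loc[list(group_b)].to_numpy()
    n_otus = rel.shape[1]
    contrib = np.zeros(n_otus)
    n_pairs = 0
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            denom = (a[i] + b[j]).sum()
            contrib += np.abs(a[i] - b[j]) / denom
            n_pairs += 1
    contrib /= n_pairs
    total = float(contrib.sum())
    degenerate = total <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = 100.0 * contrib / total if not degenerate else np.full(n_otus, np.nan)
    order = np.argsort(-contrib, kind="stable")
    df = pd.DataFrame(
        {
            "contribution": contrib,
            "percent": percent,
        },
        index=rel.columns,
    ).iloc[order]
    df["cumulative_percent"] = df["percent"].cumsum()
    df["rank"] = np.arange(1, n_otus + 1)
    return SimperResult(df, total, degenerate)


@dataclass(frozen=True)
class NmdsResult:
    """An NMDS ordination: coordinates, Kruskal stress-1, convergence info."""

    coordinates: pd.DataFrame
    stress: float
    seed: int | None
    n_restarts: int
    converged: bool
    stress_history: tuple[float, ...] = ()


def _isotonic_fit(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit to y."""
    n = len(y)
    fitted = y.astype(float).copy()
    weight = np.ones(n)
    # blocks as (value, weight) merged until monotone
    values: list[float] = []
    weights: list[float] = []
    counts: list[int] = []
    for i in range(n):
        values.append(fitted[i])
        weights.append(1.0)
        counts.append(1)
        while len(values) > 1 and values[-2] > values[-1]:
            v = (values[-2] * weights[-2] + values[-1] * weights[-1]) / (
                weights[-2] + weights[-1]
            )
            w = weights[-2] + weights[-1]
            c = counts[-2] + counts[-1]
            values = values[:-2] + [v]
            weights = weights[:-2] + [w]
            counts = counts[:-2] + [c]
    out = np.empty(n)
    pos = 0
    for v, c in zip(values, counts):
        out[pos: pos + c] = v
        pos += c
    return out


def _kruskal_stress(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = (d_config ** 2).sum()
    if denom == 0:
        return 0.0
    return math.sqrt(((disparities - d_config) ** 2).sum() / denom)


def _nmds_single(
    diss: np.ndarray,
    n: int,
    dims: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, bool, list[float]]:
    iu = np.triu_indices(n, k=1)
    diss_flat = diss[iu]
    x = rng.normal(scale=1.0, size=(n, dims))
    history: list[float] = []
    prev_stress = np.inf
    converged = False
    for _ in range(max_iter):
        d_flat = pdist(x)
        # primary (weak) tie treatment: within tie blocks order by the
        # current configuration distance, so tied dissimilarities are free
        order = np.lexsort((d_flat, diss_flat))
        disparities = np.empty_like(d_flat)
        disparities[order] = _isotonic_fit(d_flat[order])
        stress = _kruskal_stress(d_flat, disparities)
        if stress > prev_stress + 1e-12:
            break  # keep the recorded sequence non-increasing
        history.append(stress)
        if prev_stress - stress < tol:
            converged = True
            break
        prev_stress = stress
        # Guttman transform with the disparities as target distances
        dhat = squareform(disparities)
        d_mat = squareform(d_flat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_mat > 0, dhat / d_mat, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
    return x, history[-1] if history else prev_stress, converged, history


def nmds(
    dm: DistanceMatrix,
    dims: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> NmdsResult:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Alternates isotonic regression of configuration distances on
    dissimilarity ranks (primary tie treatment) with SMACOF/Guttman
    configuration updates; the best of ``n_restarts`` seeded random starts
    is returned.  Coordinates are centred; stress is dimensionless.
    """
    if dm.n < 4:
        raise ValueError("need at least 4 samples for a meaningful ordination")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_restarts)
    best: tuple[float, np.ndarray, bool, list[float]] | None = None
    for child in children:
        rng = np.random.default_rng(child)
        x, stress, conv, history = _nmds_single(
            dm.values, dm.n, dims, max_iter, tol, rng
        )
        if best is None or stress < best[0]:
            best = (stress, x, conv, history)
    assert best is not None
    stress, x, conv, history = best
    coords = pd.DataFrame(
        x, index=list(dm.labels), columns=[f"axis{k+1}" for k in range(dims)]
    )
    return NmdsResult(coords, stress, seed, n_restarts, conv, tuple(history))
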