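"""Clone-library processing: OTU binning, rarefaction and richness accounting.

Sequences from 16S rRNA clone libraries are binned into operational
taxonomic units (OTUs) at 97% average nucleotide similarity by
average-linkage (UPGMA merge criterion) agglomerative clustering of the
pairwise distance matrix.  The resulting samples × OTUs count table feeds
collector's curves, random subsampling to a common depth, and the
unique/shared richness accounting used to compare attached (ATT) and
suspended (SUS) communities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import gammaln

__all__ = [
    "SequenceRecord",
    "OtuTable",
    "read_fasta",
    "write_fasta",
    "pairwise_distance",
    "distance_matrix",
    "cluster_average_neighbor",
    "collectors_curve",
    "expected_richness",
    "subsample_table",
    "shared_richness",
]

VALID_RESIDUES = set("ACGTN-")

#: default 3% dissimilarity ≙ 97% similarity OTU definition
DEFAULT_CUTOFF = 0.03


@dataclass(frozen=True)
class SequenceRecord:
    """One clone sequence with the sample (library) it came from."""

    id: str
    sample_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        seq = self.residues.upper()
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "residues", seq)


def read_fasta(
    path: str | Path,
    sample_pattern: str = r"^(?P<sample>.+)\|(?P<clone>[^|]+)$",
) -> list[SequenceRecord]:
    """Read clone sequences from FASTA, extracting sample ids from headers.

    ``sample_pattern`` is a regex with a ``sample`` named group applied to
    each record id; a ``|``-separated ``well_fraction|clone`` convention is
    the default.  Headers that do not match keep the whole id as sample.
    """
    pattern = re.compile(sample_pattern)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        m = pattern.match(rec.id)
        sample = m.group("sample") if m else rec.id
        records.append(SequenceRecord(rec.id, sample, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def _aligned_distance(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError(
            f"aligned mode needs equal lengths ({len(a)} vs {len(b)})"
        )
    # gap-gap columns are ignored; gap-base columns count as differences
    diffs = 0
    cols = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x != y:
            diffs += 1
    if cols == 0:
        raise ValueError("no comparable columns (all gap-gap)")
    return diffs / cols


_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def _global_distance(a: str, b: str) -> float:
    aln = _ALIGNER.align(a.replace("-", ""), b.replace("-", ""))[0]
    ga, gb = str(aln[0]), str(aln[1])
    diffs = sum(1 for x, y in zip(ga, gb) if x != y)
    return diffs / len(ga)


def pairwise_distance(
    a: SequenceRecord | str, b: SequenceRecord | str, mode: str = "aligned"
) -> float:
    """Nucleotide dissimilarity in [0, 1] between two sequences.

    ``aligned``: mismatch fraction over alignment columns of pre-aligned
    input (gap-gap columns ignored, gap-base columns count as
    differences).  ``global``: Needleman-Wunsch (match 1, mismatch −1, gap
    −2), then mismatch+indel fraction over the alignment length.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a.upper()
    sb = b.residues if isinstance(b, SequenceRecord) else b.upper()
    if mode == "aligned":
        return _aligned_distance(sa, sb)
    if mode == "global":
        return _global_distance(sa, sb)
    raise ValueError(f"unknown distance mode {mode!r}")


def distance_matrix(
    seqs: Sequence[SequenceRecord], mode: str = "aligned"
) -> np.ndarray:
    """Symmetric pairwise distance matrix in input order."""
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(seqs[i], seqs[j], mode)
    return d


@dataclass
class OtuTable:
    """Samples × OTUs count table with optional sample/OTU metadata.

    ``counts``: integer DataFrame, rows = sample ids, columns = OTU ids.
    ``sample_meta``: per-sample metadata (``well_id``, ``fraction`` in
    {ATT, SUS}, ``sulfate_class``), indexed by sample id.
    ``otu_meta``: per-OTU metadata (``representative`` sequence id and an
    optional externally supplied ``taxonomy`` label), indexed by OTU id.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    otu_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(counts.values.dtype, np.integer):
            if not np.allclose(counts.values, np.round(counts.values)):
                raise ValueError("counts must be integers")
            self.counts = counts = counts.round().astype(int)
        zero_otus = counts.columns[(counts.sum(axis=0) == 0)]
        if len(zero_otus):
            raise ValueError(f"all-zero OTU columns: {list(zero_otus)[:5]}")
        if self.sample_meta is not None:
            missing = set(counts.index) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otus(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def richness(self, samples: Sequence[str] | None = None) -> int:
        """Number of OTUs with nonzero count in the (pooled) sample set."""
        sub = self.counts if samples is None else self.counts.loc[list(samples)]
        return int((sub.sum(axis=0) > 0).sum())

    def pooled_counts(self, samples: Sequence[str] | None = None) -> pd.Series:
        sub = self.counts if samples is None else self.counts.loc[list(samples)]
        return sub.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        sizes = self.library_sizes()
        if (sizes == 0).any():
            raise ValueError("sample with zero total count")
        return self.counts.div(sizes, axis=0)

    def subset_samples(self, samples: Sequence[str]) -> "OtuTable":
        counts = self.counts.loc[list(samples)]
        keep = counts.columns[counts.sum(axis=0) > 0]
        meta = (
            self.sample_meta.loc[list(samples)] if self.sample_meta is not None else None
        )
        otu_meta = self.otu_meta.loc[keep] if self.otu_meta is not None else None
        return OtuTable(counts[keep], meta, otu_meta)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(
        cls, path: str | Path, sample_meta: pd.DataFrame | None = None
    ) -> "OtuTable":
        counts = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(counts, sample_meta)


def cluster_average_neighbor(
    seqs: Sequence[SequenceRecord],
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "aligned",
    precomputed: np.ndarray | None = None,
) -> tuple[OtuTable, dict[str, str]]:
    """Bin sequences into OTUs by average-linkage clustering at ``cutoff``.

    Produces the samples × OTUs count table and a sequence-id → OTU-id
    assignment.  OTUs are labelled ``OTU_0001`` … in order of their
    lexicographically smallest member id (which is also recorded as the
    representative), making the output deterministic for a given input
    set regardless of input order.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    if not seqs:
        raise ValueError("no sequences to cluster")
    order = sorted(range(len(seqs)), key=lambda i: seqs[i].id)
    seqs = [seqs[i] for i in order]
    if precomputed is not None:
        d = np.asarray(precomputed, dtype=float)[np.ix_(order, order)]
    else:
        d = distance_matrix(seqs, mode)
    if len(seqs) == 1:
        labels = np.array([1])
    else:
        z = hierarchy.linkage(squareform(d, checks=False), method="average")
        labels = hierarchy.fcluster(z, t=cutoff, criterion="distance")

    clusters: dict[int, list[SequenceRecord]] = {}
    for rec, lab in zip(seqs, labels):
        clusters.setdefault(int(lab), []).append(rec)
    # order clusters by lexicographically smallest member id
    ordered = sorted(clusters.values(), key=lambda ms: min(m.id for m in ms))
    assignment: dict[str, str] = {}
    otu_ids, reps = [], []
    width = max(4, len(str(len(ordered))))
    for k, members in enumerate(ordered, start=1):
        otu_id = f"OTU_{k:0{width}d}"
        otu_ids.append(otu_id)
        reps.append(min(m.id for m in members))
        for m in members:
            assignment[m.id] = otu_id

    sample_ids = sorted({s.sample_id for s in seqs})
    counts = pd.DataFrame(0, index=sample_ids, columns=otu_ids, dtype=int)
    for rec in seqs:
        counts.loc[rec.sample_id, assignment[rec.id]] += 1
    otu_meta = pd.DataFrame({"representative": reps}, index=otu_ids)
    return OtuTable(counts, otu_meta=otu_meta), assignment


def collectors_curve(
    counts: Sequence[int] | pd.Series,
    order: Sequence[int] | None = None,
    seed: int | None = None,
) -> list[tuple[int, int]]:
    """Observed richness as sequences accumulate (collector's curve).

    ``counts`` is the pooled per-OTU count vector.  The arrival order is
    either given explicitly as a sequence of OTU indices (one per
    sequence) or drawn as a seeded uniform shuffle of the pool.  The curve
    is monotone non-decreasing and ends at the pool's total richness.
    """
    vec = np.asarray(counts, dtype=int)
    if vec.sum() < 1:
        raise ValueError("empty pool")
    if order is None:
        pool = np.repeat(np.arange(len(vec)), vec)
        rng = np.random.default_rng(seed)
        rng.shuffle(pool)
    else:
        pool = np.asarray(order, dtype=int)
        if len(pool) != vec.sum():
            raise ValueError("arrival order length differs from pool size")
    seen: set[int] = set()
    curve = []
    for k, otu in enumerate(pool, start=1):
        seen.add(int(otu))
        curve.append((k, len(seen)))
    return curve


def expected_richness(counts: Sequence[int] | pd.Series, depth: int) -> float:
    """Closed-form rarefaction: E[OTUs] in a without-replacement draw.

    E[S(d)] = Σ_j (1 − C(N−n_j, d)/C(N, d)) for pool size N and per-OTU
    counts n_j (hypergeometric expectation), evaluated with log-gamma for
    numerical stability.
    """
    vec = np.asarray(counts, dtype=int)
    vec = vec[vec > 0]
    n_total = int(vec.sum())
    if not (0 <= depth <= n_total):
        raise ValueError(f"depth {depth} outside [0, {n_total}]")

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = n_total - vec
    with np.errstate(invalid="ignore"):
        log_p_absent = np.where(
            rest >= depth, log_comb(rest, depth) - log_comb(n_total, depth), -np.inf
        )
    return float(np.sum(1.0 - np.exp(log_p_absent)))


def subsample_table(
    table: OtuTable,
    pool: Sequence[str],
    depth: int,
    seed: int | None = None,
    pooled_id: str = "pooled",
) -> OtuTable:
    """Draw ``depth`` sequences without replacement from a pooled sample set.

    Returns a one-row OtuTable of the subsampled pool (all-zero OTU
    columns dropped), reproducible for a given ``seed``.  Used to
    normalize richness comparisons to a common sequencing depth.
    """
    vec = table.pooled_counts(pool)
    total = int(vec.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds pooled total {total}")
    rng = np.random.default_rng(seed)
    draw = rng.multivariate_hypergeometric(vec.to_numpy(), depth)
    counts = pd.DataFrame([draw], index=[pooled_id], columns=vec.index)
    keep = counts.columns[counts.iloc[0] > 0]
    return OtuTable(counts[keep])


def shared_richness(
    table: OtuTable, group_a: Sequence[str], group_b: Sequence[str]
) -> dict[str, float]:
    """Unique and shared OTU richness between two disjoint sample groups.

    Reports per-group richness, the number of OTUs detected in both
    groups, the percentage of each group's OTUs that are shared, and the
    percentage of each group's sequences falling in shared OTUs.
    """
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise ValueError("both groups must be non-empty")
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)}")
    pooled_a = table.pooled_counts(list(group_a))
    pooled_b = table.pooled_counts(list(group_b))
    present_a = pooled_a[pooled_a > 0].index
    present_b = pooled_b[pooled_b > 0].index
    shared = present_a.intersection(present_b)
    seqs_a, seqs_b = int(pooled_a.sum()), int(pooled_b.sum())
    return {
        "otus_a": int(len(present_a)),
        "otus_b": int(len(present_b)),
        "shared_otus": int(len(shared)),
        "pct_otus_shared_a": 100.0 * len(shared) / len(present_a) if len(present_a) else 0.0,
        "pct_otus_shared_b": 100.0 * len(shared) / len(present_b) if len(present_b) else 0.0,
        "pct_seqs_in_shared_a": 100.0 * pooled_a[shared].sum() / seqs_a if seqs_a else 0.0,
        "pct_seqs_in_shared_b": 100.0 * pooled_b[shared].sum() / seqs_b if seqs_b else 0.0,
    }
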