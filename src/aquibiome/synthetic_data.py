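"""Synthetic well chemistry, clone libraries and OTU tables for testing.

The study design being emulated: ~25 monitoring wells split into high
(HS), low (LS) and negligible (NS) sulfate zones, each sampled for an
attached (ATT, in situ sediment sampler) and a suspended (SUS, pumped
groundwater) microbial fraction, with clone libraries of ~192 sequences
per sample.  Chemistry tables reproduce the zone-defining sulfate ranges
and the inverse methane-sulfate relationship; OTU tables are drawn from a
Dirichlet-multinomial with planted multiplicative (log-fold) enrichment
of designated OTU blocks per fraction/zone, so every downstream statistic
has a known ground truth.  All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geochem import Measurement, SulfateClass, WellChemistry, classify_sulfate
from .otu import OtuTable, SequenceRecord

__all__ = [
    "ChemistrySpec",
    "gen_chemistry",
    "EffectBlock",
    "CommunitySpec",
    "gen_otu_table",
    "gen_sequences",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChemistrySpec:
    """Ranges for synthetic well chemistry, per sulfate zone.

    Sulfate ranges (mM) must stay inside their zone's classification
    interval (HS > 0.2, LS in (0.03, 0.2], NS ≤ 0.03) and must not
    overlap.  Methane ranges (µM) are inversely tied to the zones: NS
    wells methane-rich (≥ 100 µM), HS wells methane-poor (≤ 20 µM).
    Hydrogen is log-uniform over its survey range.
    """

    n_wells: Mapping[str, int] = field(
        default_factory=lambda: {"HS": 9, "LS": 8, "NS": 8}
    )
    so4_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "HS": (0.4, 11.0),
            "LS": (0.04, 0.2),
            "NS": (0.005, 0.03),
        }
    )
    ch4_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "HS": (0.2, 20.0),
            "LS": (3.0, 50.0),
            "NS": (100.0, 1240.0),
        }
    )
    h2_range_nm: tuple[float, float] = (3.0, 240.0)
    temp_range: tuple[float, float] = (12.0, 16.0)
    ph_range: tuple[float, float] = (7.1, 7.9)
    dic_range: tuple[float, float] = (5.0, 9.0)
    spec_cond_range: tuple[float, float] = (600.0, 1300.0)
    seed: int = 0

    def validate(self) -> None:
        intervals = sorted(self.so4_ranges.items(), key=lambda kv: kv[1][0])
        for (cls_a, (lo_a, hi_a)), (cls_b, (lo_b, hi_b)) in zip(
            intervals, intervals[1:]
        ):
            if hi_a > lo_b:
                raise ValueError(
                    f"sulfate ranges overlap: {cls_a} {(lo_a, hi_a)} vs "
                    f"{cls_b} {(lo_b, hi_b)}"
                )
        for cls, (lo, hi) in self.so4_ranges.items():
            if lo > hi:
                raise ValueError(f"{cls}: inverted sulfate range")
            for probe in (lo, hi):
                if classify_sulfate(probe).value != cls:
                    raise ValueError(
                        f"{cls}: sulfate range endpoint {probe} classifies as "
                        f"{classify_sulfate(probe).value}"
                    )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))


def gen_chemistry(spec: ChemistrySpec = ChemistrySpec()) -> list[WellChemistry]:
    """Generate a synthetic well-chemistry table for the spec's zones.

    Sulfate and methane are drawn log-uniformly inside their per-zone
    ranges (giving the inverse CH4-SO4 relationship across zones by
    construction); hydrogen, temperature, pH, DIC and conductance are
    zone-independent.  Wells are labelled ``HS01`` ... ``NS08`` and
    re-classifying their sulfate recovers the generating zone exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    wells: list[WellChemistry] = []
    for cls in ("HS", "LS", "NS"):
        n = spec.n_wells.get(cls, 0)
        so4 = _log_uniform(rng, *spec.so4_ranges[cls], n)
        ch4 = _log_uniform(rng, *spec.ch4_ranges[cls], n)
        h2 = _log_uniform(rng, *spec.h2_range_nm, n)
        temp = rng.uniform(*spec.temp_range, size=n)
        ph = rng.uniform(*spec.ph_range, size=n)
        dic = rng.uniform(*spec.dic_range, size=n)
        cond = rng.uniform(*spec.spec_cond_range, size=n)
        for k in range(n):
            wells.append(
                WellChemistry(
                    well_id=f"{cls}{k + 1:02d}",
                    temperature=round(float(temp[k]), 1),
                    ph=round(float(ph[k]), 1),
                    spec_cond=Measurement(round(float(cond[k]), 0)),
                    so4=Measurement(float(so4[k])),
                    ch4_aq=Measurement(float(ch4[k])),
                    h2_aq=Measurement(float(h2[k])),
                    dic=Measurement(round(float(dic[k]), 1)),
                )
            )
    return wells


@dataclass(frozen=True)
class EffectBlock:
    """A planted enrichment: a block of OTUs up- or down-weighted in the
    samples matching ``fraction`` and/or ``sulfate_class`` (None = any).

    ``log_fold`` is the natural-log multiplicative shift applied to the
    block's Dirichlet concentrations in matching samples.
    """

    name: str
    otu_indices: tuple[int, ...]
    log_fold: float
    fraction: str | None = None
    sulfate_class: str | None = None

    def applies(self, fraction: str, sulfate_class: str) -> bool:
        if self.fraction is not None and self.fraction != fraction:
            return False
        if self.sulfate_class is not None and self.sulfate_class != sulfate_class:
            return False
        return True


def _default_effects() -> tuple[EffectBlock, ...]:
    # mirrors the field structure: an iron-reducer-like block enriched on
    # sediment (ATT), a sulfate-reducer-like block enriched in HS wells,
    # a methanogen-like block enriched in NS wells, and a methane-oxidizer
    # (ANME-like) block enriched in suspended LS samples
    return (
        EffectBlock("iron_reducers", tuple(range(0, 10)), math.log(20.0), fraction="ATT"),
        EffectBlock("sulfate_reducers", tuple(range(10, 20)), math.log(8.0), sulfate_class="HS"),
        EffectBlock("methanogens", tuple(range(20, 30)), math.log(30.0), sulfate_class="NS"),
        EffectBlock("methane_oxidizers", tuple(range(30, 40)), math.log(12.0),
                    fraction="SUS", sulfate_class="LS"),
    )


def fraction_contrast_effects(strength: float = math.log(20.0)) -> tuple[EffectBlock, ...]:
    """A strong two-sided ATT/SUS contrast for planted-effect recovery.

    Mirrors the reciprocal enrichment seen between aquifer fractions in
    the field (iron-/sulfate-reducer-like taxa concentrated on sediment,
    other Proteobacteria-like taxa in groundwater): one 10-OTU block
    up-weighted in ATT samples and a disjoint 10-OTU block up-weighted in
    SUS samples, each by ``strength`` natural-log units.
    """
    return (
        EffectBlock("att_enriched", tuple(range(0, 10)), strength, fraction="ATT"),
        EffectBlock("sus_enriched", tuple(range(10, 20)), strength, fraction="SUS"),
    )


@dataclass(frozen=True)
class CommunitySpec:
    """Design of a synthetic clone-library experiment.

    ``n_wells`` per sulfate zone; every well contributes one sample per
    fraction in ``fractions``; each sample's composition is
    Dirichlet(base_concentration × exp(effects)) and its counts are
    multinomial with the given library size (192 clones per library by
    default, the study's minimum sequencing depth).
    """

    n_wells: Mapping[str, int] = field(
        default_factory=lambda: {"HS": 3, "LS": 3, "NS": 3}
    )
    fractions: tuple[str, ...] = ("ATT", "SUS")
    library_size: int = 192
    n_otus: int = 300
    base_concentration: float | Sequence[float] = 0.3
    effects: tuple[EffectBlock, ...] = field(default_factory=_default_effects)
    seed: int = 0

    def validate(self) -> None:
        if self.n_otus < 1 or self.library_size < 1:
            raise ValueError("n_otus and library_size must be positive")
        used: set[int] = set()
        for block in self.effects:
            if max(block.otu_indices, default=-1) >= self.n_otus:
                raise ValueError(
                    f"effect block {block.name!r} exceeds n_otus={self.n_otus}"
                )
            overlap = used & set(block.otu_indices)
            if overlap:
                raise ValueError(
                    f"effect blocks overlap at OTU indices {sorted(overlap)[:5]}"
                )
            used |= set(block.otu_indices)
        alpha = self.base_alpha()
        if (alpha <= 0).any():
            raise ValueError("base concentrations must be positive")

    def base_alpha(self) -> np.ndarray:
        if np.isscalar(self.base_concentration):
            return np.full(self.n_otus, float(self.base_concentration))
        alpha = np.asarray(self.base_concentration, dtype=float)
        if alpha.shape != (self.n_otus,):
            raise ValueError("base concentration vector length != n_otus")
        return alpha

    def null(self) -> "CommunitySpec":
        """The same design with all planted effects removed."""
        return replace(self, effects=())


def gen_otu_table(spec: CommunitySpec = CommunitySpec()) -> OtuTable:
    """Draw a samples × OTUs count table under the spec's planted design.

    Sample ids are ``{zone}{well:02d}_{fraction}``; sample metadata
    carries well_id, fraction and sulfate_class.  Every sample's row sum
    equals the library size exactly.  OTUs never observed in any sample
    are dropped (the table invariant), so downstream richness reflects
    detected OTUs, as in a real clone library.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = spec.base_alpha()
    rows, meta_rows, ids = [], [], []
    for cls in ("HS", "LS", "NS"):
        for w in range(spec.n_wells.get(cls, 0)):
            well_id = f"{cls}{w + 1:02d}"
            for fraction in spec.fractions:
                alpha = base.copy()
                for block in spec.effects:
                    if block.applies(fraction, cls):
                        alpha[list(block.otu_indices)] *= math.exp(block.log_fold)
                p = rng.dirichlet(alpha)
                counts = rng.multinomial(spec.library_size, p)
                ids.append(f"{well_id}_{fraction}")
                rows.append(counts)
                meta_rows.append(
                    {"well_id": well_id, "fraction": fraction, "sulfate_class": cls}
                )
    otu_ids = [f"OTU_{k + 1:04d}" for k in range(spec.n_otus)]
    counts = pd.DataFrame(rows, index=ids, columns=otu_ids, dtype=int)
    observed = counts.columns[counts.sum(axis=0) > 0]
    counts = counts[observed]
    meta = pd.DataFrame(meta_rows, index=ids)
    return OtuTable(counts, sample_meta=meta)


def gen_sequences(
    n_clusters: int,
    members_per_cluster: int,
    within_divergence: float = 0.01,
    between_divergence: float = 0.10,
    length: int = 250,
    seed: int = 0,
    sample_cycle: Sequence[str] = ("sample1",),
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Planted-cluster sequence sets for exercising the OTU binner.

    A random ancestor is drawn per cluster (rejecting ancestor pairs
    closer than ``between_divergence``); each member is the ancestor with
    per-site substitutions at rate ``within_divergence``.  Returns the
    records (ids ``C{cluster}_{member}``, samples assigned round-robin
    from ``sample_cycle``) and the true cluster label per sequence id.
    """
    if not (0.0 <= within_divergence < between_divergence <= 0.75):
        raise ValueError(
            "need 0 ≤ within_divergence < between_divergence ≤ 0.75"
        )
    rng = np.random.default_rng(seed)
    ancestors: list[np.ndarray] = []
    attempts = 0
    while len(ancestors) < n_clusters:
        cand = rng.integers(0, 4, size=length)
        if all(np.mean(cand != a) > between_divergence for a in ancestors):
            ancestors.append(cand)
        attempts += 1
        if attempts > 100 * n_clusters + 100:
            raise ValueError("cannot place ancestors this far apart; shorten the list")
    records: list[SequenceRecord] = []
    truth: dict[str, int] = {}
    k = 0
    for c, anc in enumerate(ancestors):
        for m in range(members_per_cluster):
            seq = anc.copy()
            hits = rng.random(length) < within_divergence
            # substitute with a different base at each hit site
            shift = rng.integers(1, 4, size=int(hits.sum()))
            seq[hits] = (seq[hits] + shift) % 4
            sid = f"C{c + 1:02d}_{m + 1:03d}"
            records.append(
                SequenceRecord(
                    sid,
                    sample_cycle[k % len(sample_cycle)],
                    "".join(_BASES[seq]),
                )
            )
            truth[sid] = c
            k += 1
    return records, truth
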