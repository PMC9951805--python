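"""Dietary niche statistics from frequency-of-occurrence composition data.

Given per-species food-item occurrence counts (FO), this module computes

* relative frequency of occurrence, RFO_i = 100 · FO_i / Σ FO,
* Levins niche breadth  L = 1 / Σ p_i²  and its standardisation
  Lst = (L − 1)/(n − 1) ∈ [0, 1],
* Shannon diversity  H′ = −Σ p_i ln p_i  (natural log),
* Pielou evenness  E = H′ / ln S  with S the richness (items with FO > 0),
* Pianka's niche overlap  O_jk = Σ p_ij p_ik / √(Σ p_ij² Σ p_ik²)
  between two species' diet proportion vectors.

By default the item universe is *every* category recovered from scats,
including non-food residues (grit, artificial matter); ``exclude_nonfood``
drops the 'other' group before computing anything.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core_io import CompositionTable, DataError

__all__ = [
    "ProportionVector",
    "NicheMetrics",
    "relative_frequency",
    "levins_breadth",
    "standardized_breadth",
    "shannon_diversity",
    "evenness",
    "richness",
    "pianka_overlap",
    "species_metrics",
    "diet_report",
]


@dataclass(frozen=True)
class ProportionVector:
    """Diet proportions over an ordered item universe; sums to 1."""

    labels: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or len(p) != len(self.labels) or len(p) < 1:
            raise DataError("proportion vector shape mismatch")
        if (p < 0).any():
            raise DataError("proportions must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise DataError(f"proportions must sum to 1, got {p.sum()!r}")
        object.__setattr__(self, "p", p)

    @classmethod
    def from_counts(cls, fo: pd.Series) -> "ProportionVector":
        fo = fo.astype(float)
        total = fo.sum()
        if total <= 0:
            raise DataError("all-zero FO column")
        return cls(labels=tuple(fo.index), p=(fo / total).to_numpy())

    @property
    def rfo(self) -> pd.Series:
        """Relative frequency of occurrence in percent (full precision)."""
        return pd.Series(100.0 * self.p, index=list(self.labels), name="rfo")


@dataclass(frozen=True)
class NicheMetrics:
    """Per-species dietary niche summary."""

    L: float  # Levins breadth, 1..S
    Lst: float  # standardised breadth, 0..1
    H: float  # Shannon diversity, nats
    E: float  # Pielou evenness, 0..1
    S: int  # richness: items with FO > 0

    def as_dict(self) -> dict:
        return asdict(self)


def relative_frequency(fo: pd.Series) -> ProportionVector:
    """Proportion vector p_i = FO_i / Σ FO from an occurrence-count column."""
    return ProportionVector.from_counts(fo)


def levins_breadth(p: ProportionVector | np.ndarray) -> float:
    """Levins niche breadth L = 1 / Σ p_i² (inverse Simpson concentration)."""
    arr = p.p if isinstance(p, ProportionVector) else np.asarray(p, dtype=float)
    return float(1.0 / np.sum(arr**2))


def standardized_breadth(L: float, n: int) -> float:
    """Standardised Levins breadth Lst = (L − 1) / (n − 1), in [0, 1]."""
    if n < 2:
        raise DataError(f"standardised breadth undefined for n = {n} (< 2 items)")
    if not (1.0 - 1e-9 <= L <= n + 1e-9):
        raise DataError(f"L = {L} outside [1, n = {n}]")
    return float((L - 1.0) / (n - 1.0))


def shannon_diversity(p: ProportionVector | np.ndarray) -> float:
    """Shannon diversity H′ = −Σ p_i ln p_i in nats; 0·ln 0 taken as 0."""
    arr = p.p if isinstance(p, ProportionVector) else np.asarray(p, dtype=float)
    nz = arr[arr > 0]
    return float(-(nz * np.log(nz)).sum())


def evenness(H: float, S: int) -> float:
    """Pielou evenness E = H′ / ln S; needs richness S ≥ 2."""
    if S < 2:
        raise DataError(f"evenness undefined for richness S = {S} (< 2)")
    return float(H / np.log(S))


def richness(fo: pd.Series) -> int:
    """Richness S: number of categories actually used (FO > 0)."""
    return int((fo > 0).sum())


def pianka_overlap(p_j, p_k) -> float:
    """Pianka's niche overlap O_jk between two resource-use vectors.

    Accepts :class:`ProportionVector`\\ s (aligned on the union of their
    labels, absent items as 0), pandas Series (aligned the same way), or
    plain aligned arrays.  Invariant to rescaling either vector, symmetric,
    and in [0, 1] with 1 iff the vectors are proportional.
    """
    u, v = _align(p_j, p_k)
    nu, nv = np.sqrt((u**2).sum()), np.sqrt((v**2).sum())
    if nu == 0 or nv == 0:
        raise DataError("Pianka overlap undefined for an all-zero vector")
    return float((u * v).sum() / (nu * nv))


def _align(a, b) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, ProportionVector):
        a = pd.Series(a.p, index=list(a.labels))
    if isinstance(b, ProportionVector):
        b = pd.Series(b.p, index=list(b.labels))
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        universe = a.index.union(b.index)
        return (
            a.reindex(universe, fill_value=0.0).to_numpy(dtype=float),
            b.reindex(universe, fill_value=0.0).to_numpy(dtype=float),
        )
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("unlabelled vectors must be pre-aligned to equal length")
    return a, b


def species_metrics(fo: pd.Series) -> NicheMetrics:
    """All niche-breadth/diversity metrics for one species' FO column.

    The item universe for L, Lst, H′, E is the set of categories the species
    actually used (FO > 0), which equals the richness S.
    """
    used = fo[fo > 0]
    S = richness(fo)
    p = relative_frequency(used)
    L = levins_breadth(p)
    H = shannon_diversity(p)
    return NicheMetrics(
        L=L,
        Lst=standardized_breadth(L, S) if S >= 2 else float("nan"),
        H=H,
        E=evenness(H, S) if S >= 2 else float("nan"),
        S=S,
    )


def group_subtotals(table: CompositionTable, species: str) -> pd.DataFrame:
    """Per-group FO and RFO(%) subtotals, derived from the rows.

    Subtotals are always recomputed by summing item rows; a printed subtotal
    cell is never trusted.
    """
    fo = table.fo(species)
    total = fo.sum()
    agg = fo.groupby(table.groups).sum()
    agg = agg.reindex([g for g in CompositionTable.GROUPS if g in agg.index])
    return pd.DataFrame({"fo": agg.astype(int), "rfo": 100.0 * agg / total})


def diet_report(table: CompositionTable, exclude_nonfood: bool = False) -> dict:
    """Full dietary report: per-item RFO, group subtotals, per-species
    niche metrics, and all pairwise Pianka overlaps.

    ``exclude_nonfood`` drops the 'other' group (grit, artificial matter)
    from the item universe before any computation.  Numbers are returned at
    full precision; display rounding (RFO 1 d.p., indices 2 d.p.) is left to
    the presentation layer.
    """
    if len(table.species) < 2:
        raise DataError("diet report needs at least two species columns")
    if exclude_nonfood:
        df = table.df[table.df["group"] != "other"]
        table = CompositionTable(df)

    report: dict = {"species": {}, "overlap": {}, "items": {}, "subtotals": {}}
    props: dict[str, pd.Series] = {}
    for sp in table.species:
        fo = table.fo(sp)
        pv = relative_frequency(fo)
        props[sp] = pd.Series(pv.p, index=list(pv.labels))
        report["species"][sp] = species_metrics(fo).as_dict()
        report["items"][sp] = {
            "fo": fo.to_dict(),
            "rfo": pv.rfo.to_dict(),
        }
        report["subtotals"][sp] = group_subtotals(table, sp)["rfo"].to_dict()
    species = table.species
    for i, sp1 in enumerate(species):
        for sp2 in species[i + 1 :]:
            report["overlap"][f"{sp1}|{sp2}"] = pianka_overlap(props[sp1], props[sp2])
    return report
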