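"""Spatial niche overlap from camera-trap detection frequencies.

Each species' use of space is summarised as the share of its independent
detections occurring at each camera site (p_ij = detections of species j at
site i / total detections of species j).  Pianka's index on the two share
vectors then measures spatial overlap: 0 = fully disjoint site use,
1 = identical relative use of sites.

Sites where neither species was detected stay in the matrix — they carry no
weight in the index but are part of the deployment and are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ConfigurationError, DataError, DetectionTable
from .diet_metrics import pianka_overlap

__all__ = ["SiteFrequencyMatrix", "OverlapResult", "site_frequency_matrix", "spatial_pianka"]


@dataclass(frozen=True)
class OverlapResult:
    """An overlap coefficient with the metadata needed to interpret it."""

    estimator: str
    value: float
    n1: int
    n2: int
    classification: str | None = None

    def as_dict(self) -> dict:
        d = {"estimator": self.estimator, "value": self.value, "n1": self.n1, "n2": self.n2}
        if self.classification is not None:
            d["class"] = self.classification
        return d


class SiteFrequencyMatrix:
    """Site × species independent-detection counts and per-species shares."""

    def __init__(self, counts: pd.DataFrame):
        if (counts < 0).any().any():
            raise DataError("detection counts must be >= 0")
        self.counts = counts.astype(float)

    @property
    def sites(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def p(self) -> pd.DataFrame:
        """Relative frequency per species: each column sums to 1."""
        totals = self.counts.sum(axis=0)
        return self.counts / totals

    def n_detections(self, species: str) -> int:
        return int(self.counts[species].sum())

    def occupancy(self) -> pd.Series:
        """Number of sites with >= 1 detection, per species."""
        return (self.counts > 0).sum(axis=0)


def site_frequency_matrix(
    detections: DetectionTable,
    sites: Sequence[str] | None = None,
    effort: pd.Series | None = None,
) -> SiteFrequencyMatrix:
    """Sum detections per species per site into a frequency matrix.

    Parameters
    ----------
    detections
        Ideally independence-filtered; a warning is issued for raw data.
    sites
        Full deployment site list.  Sites without any detection are kept as
        zero rows; detections at a site absent from the list are an error.
    effort
        Optional per-site effort (e.g. camera-days).  When given, counts are
        divided by effort before the per-species normalisation, so unequal
        deployments do not masquerade as preference.
    """
    if not detections.is_filtered:
        warnings.warn(
            "building site frequencies from raw (unfiltered) detections; "
            "apply filter_independent() first to avoid pseudo-replication",
            stacklevel=2,
        )
    df = detections.to_frame()
    counts = df.groupby(["site", "species"]).size().unstack(fill_value=0)
    if sites is not None:
        unknown = set(counts.index) - set(sites)
        if unknown:
            raise DataError(f"detections at sites not in the deployment list: {sorted(unknown)}")
        counts = counts.reindex(list(sites), fill_value=0)
    zero_species = [sp for sp in counts.columns if counts[sp].sum() == 0]
    if zero_species:
        raise DataError(f"species with zero detections: {zero_species}")
    counts = counts.astype(float)
    if effort is not None:
        effort = effort.reindex(counts.index)
        if effort.isna().any() or (effort <= 0).any():
            raise ConfigurationError("effort must be positive and cover every site")
        counts = counts.div(effort, axis=0)
    return SiteFrequencyMatrix(counts)


def spatial_pianka(matrix: SiteFrequencyMatrix, sp1: str, sp2: str) -> OverlapResult:
    """Pianka spatial overlap between two species' site-use share vectors."""
    for sp in (sp1, sp2):
        if sp not in matrix.species:
            raise ConfigurationError(f"species {sp!r} not in matrix (have {matrix.species})")
    value = pianka_overlap(matrix.p[sp1], matrix.p[sp2])
    return OverlapResult(
        estimator="pianka",
        value=value,
        n1=int(round(matrix.counts[sp1].sum())),
        n2=int(round(matrix.counts[sp2].sum())),
    )
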