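"""Community reference proteomes and their chemical metrics.

For each sample, the community reference proteome is the abundance-weighted
mean of the reference compositions of the taxa detected in that sample:

    aa_community = sum_t w_t * aa_t / sum_t w_t

with weights w_t the mapped lowest-level read counts.  It is an *inferred*
proteome — a statement about the genomes present, not about protein
expression.  Because reference compositions are stored per protein, every
derived metric remains interpretable as a per-protein expectation, and all
metrics are invariant to rescaling a sample's counts.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .chem import (
    AminoAcidComposition,
    BasisSet,
    QEC_BASIS,
    canonical_metric,
    metrics_suite,
    weighted_mean_composition,
)
from .ingest import ClassificationTable
from .mapping import TaxonMapping
from .refdb import ReferenceProteomeDB

logger = logging.getLogger(__name__)

__all__ = ["EmptyCommunityError", "DEFAULT_METRICS", "community_composition", "get_metrics"]

#: Metrics computed when the caller does not choose.
DEFAULT_METRICS: tuple[str, ...] = ("Zc", "nO2", "nH2O")


class EmptyCommunityError(ValueError):
    """A sample has no mapped, nonzero counts to aggregate."""


def community_composition(
    ct: ClassificationTable,
    mapping: TaxonMapping,
    refdb: ReferenceProteomeDB,
    sample: str,
) -> AminoAcidComposition:
    """Abundance-weighted mean reference composition for one sample.

    Unmapped rows are excluded (their loss is visible in the mapping
    report); the result has ``chains = 1`` — the mean composition of a
    single protein drawn from the community.
    """
    if sample not in ct.counts.columns:
        raise KeyError(f"unknown sample: {sample!r}")
    col = ct.counts[sample].to_numpy(dtype=float)
    comps: list[AminoAcidComposition] = []
    weights: list[float] = []
    for i, target in enumerate(mapping.targets):
        if target is None or col[i] == 0:
            continue
        comps.append(refdb[target].composition)
        weights.append(col[i])
    if not comps:
        raise EmptyCommunityError(f"sample {sample!r} has no mapped, nonzero counts")
    return weighted_mean_composition(comps, weights)


def get_metrics(
    ct: ClassificationTable,
    mapping: TaxonMapping,
    refdb: ReferenceProteomeDB,
    which: Iterable[str] | None = None,
    metadata: pd.DataFrame | None = None,
    include_terminal_water: bool = False,
    basis: BasisSet = QEC_BASIS,
) -> pd.DataFrame:
    """Chemical metrics of the community reference proteome, per sample.

    Returns a DataFrame indexed by sample name with one column per
    requested metric (default Zc, nO2, nH2O), optionally joined with
    sample metadata.  A sample with no mapped counts is omitted with a
    warning rather than aborting the table.
    """
    names = list(DEFAULT_METRICS) if which is None else [canonical_metric(n) for n in which]
    rows: dict[str, dict[str, float]] = {}
    for sample in ct.sample_names:
        try:
            comp = community_composition(ct, mapping, refdb, sample)
        except EmptyCommunityError:
            logger.warning("sample %r has no mapped counts; omitted from the metrics table", sample)
            continue
        rows[sample] = metrics_suite(
            comp, which=names, include_terminal_water=include_terminal_water, basis=basis
        )
    mt = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    mt.index.name = "sample"

    if metadata is not None:
        strays = [s for s in mt.index if s not in metadata.index]
        if strays:
            raise ValueError(f"samples missing from metadata: {strays}")
        mt = mt.join(metadata, how="left")
    return mt
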