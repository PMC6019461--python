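"""End-to-end processing of a MAF dataset, shared by the CLI and tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import annotate_records, separate_spikeins
from .clonotyping import Clonotype, ClonotypingParams, cluster_clonotypes
from .correction import CorrectedRecord, correct_dataset, group_by_rid
from .germline import GermlineDatabase
from .preprocess import LayoutConfig, parse_reads, quality_length_filter
from .standards import SpikeInSet


@dataclass
class PipelineResult:
    parsed_count: int
    filter_stats: dict
    parse_rejects: dict
    grouping: object
    corrected: list[CorrectedRecord]
    annotated: pd.DataFrame
    clonotypes: list[Clonotype]


def run_sample(
    reads: Iterable[tuple[str, str, str]],
    db: GermlineDatabase,
    config: LayoutConfig,
    standards: SpikeInSet | None = None,
    identifier: str | None = None,
    min_mean_q: float = 25.0,
    length_range: tuple[int, int] = (300, 600),
    min_reads_for_consensus: int = 3,
    strict: bool = False,
    merge_near_rids: bool = False,
    clonotyping_params: ClonotypingParams | None = None,
    replicate_id: int | None = None,
    cluster: bool = True,
) -> PipelineResult:
    """Filter, parse, UID-correct, annotate and (optionally) cluster one
    sample's pre-merged reads."""
    kept, fstats = quality_length_filter(reads, min_mean_q, length_range)
    parsed, rejects = parse_reads(kept, config)
    groups, grouping = group_by_rid(parsed, merge_near_rids=merge_near_rids)
    corrected = correct_dataset(groups, min_reads_for_consensus, strict=strict)
    annotated = annotate_records(corrected, db, config, replicate_id=replicate_id)
    if identifier is not None:
        annotated = separate_spikeins(annotated, identifier, standards)
    clonotypes = []
    if cluster and not annotated.empty:
        bio = annotated
        if "is_spikein" in annotated.columns:
            bio = annotated[~annotated["is_spikein"]]
        if not bio.empty:
            clonotypes = cluster_clonotypes(bio, clonotyping_params)
    return PipelineResult(
        parsed_count=len(parsed),
        filter_stats=fstats,
        parse_rejects=rejects,
        grouping=grouping,
        corrected=corrected,
        annotated=annotated,
        clonotypes=clonotypes,
    )
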