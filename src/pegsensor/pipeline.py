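"""End-to-end library design: variants -> ranked pegRNA-sensor designs."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .design import (
    FilterConfig,
    MAX_PER_VARIANT,
    PBS_GRID,
    RTT_GRID,
    DesignRejection,
    PegRNADesign,
    apply_filters,
    build_pegrna,
    enumerate_protospacers,
    composite_score,
    rank_and_select,
)
from .sensor import SensorWindowError, build_sensor
from .specificity import mit_specificity
from .variant_io import GeneModel, Variant


@dataclass
class DesignParams:
    rtt_grid: tuple = RTT_GRID
    pbs_grid: tuple = PBS_GRID
    max_per_variant: int = MAX_PER_VARIANT
    prepend_g: bool = True
    weights: dict | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    #: optional surrogate genome {name: seq} enabling the MIT specificity
    #: filter; when None, protospacers stay unscored and the filter is off.
    specificity_reference: dict | None = None
    #: optional external on-target scores keyed by (seq20); absent scores
    #: contribute 0 to the composite score (Rule Set 2 is consumed, not
    #: reimplemented).
    ontarget_scores: dict | None = None


def design_variant(
    variant: Variant, gene_model: GeneModel, params: DesignParams | None = None
) -> tuple[list[PegRNADesign], dict]:
    """All ranked, passing designs for one variant plus a tally of drops."""
    params = params or DesignParams()
    report = {
        "variant_id": variant.id,
        "n_protospacers": 0,
        "n_candidates": 0,
        "n_rejected": 0,
        "n_filtered": 0,
        "n_selected": 0,
    }
    protospacers = enumerate_protospacers(
        gene_model, variant, max_rtt=max(params.rtt_grid)
    )
    if params.specificity_reference or params.ontarget_scores:
        scored = []
        for proto in protospacers:
            spec = (
                mit_specificity(proto, params.specificity_reference)
                if params.specificity_reference
                else None
            )
            ont = (params.ontarget_scores or {}).get(proto.seq20)
            scored.append(
                type(proto)(
                    seq20=proto.seq20, strand=proto.strand, pam=proto.pam,
                    nick_pos=proto.nick_pos, specificity_score=spec,
                    ontarget_score=ont,
                )
            )
        protospacers = scored
    report["n_protospacers"] = len(protospacers)
    filters = params.filters
    if params.specificity_reference and not filters.specificity:
        filters = FilterConfig(**{**filters.__dict__, "specificity": True})
    candidates = []
    for proto in protospacers:
        for rtt_len in params.rtt_grid:
            for pbs_len in params.pbs_grid:
                try:
                    design = build_pegrna(
                        proto, variant, gene_model, rtt_len, pbs_len,
                        prepend_g=params.prepend_g,
                    )
                    design.sensor = build_sensor(design, gene_model, variant)
                except (DesignRejection, SensorWindowError):
                    report["n_rejected"] += 1
                    continue
                apply_filters(design, filters)
                composite_score(design, params.weights)
                candidates.append(design)
    report["n_candidates"] = len(candidates)
    report["n_filtered"] = sum(1 for d in candidates if d.filter_flags)
    selected = rank_and_select(candidates, params.max_per_variant)
    report["n_selected"] = len(selected)
    return selected, report


def design_library(
    gene_model: GeneModel,
    variants: list[Variant],
    params: DesignParams | None = None,
) -> tuple[list[PegRNADesign], pd.DataFrame]:
    """Ranked designs for a variant set plus a per-variant design report."""
    params = params or DesignParams()
    designs: list[PegRNADesign] = []
    reports = []
    for variant in variants:
        selected, report = design_variant(variant, gene_model, params)
        designs.extend(selected)
        reports.append(report)
    return designs, pd.DataFrame(reports)
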