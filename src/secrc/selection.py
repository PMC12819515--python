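"""Master-transcription-factor selection by multi-evidence integration.

Candidate TFs surviving the CRC specificity filter are scored on three
independent lines of evidence: (1) their associated super-enhancer
contains fusion-TF-bound GGAA microsatellite peaks in a majority of
evaluable samples, (2) their expression is specific to the case entity,
and (3) they score as CRISPR dependencies in the case lineage (negative
lineage T-statistic). A TF is selected as a putative MTF when it meets
at least two of the three criteria. The module also provides the
SE/dependency overlap summary and the top-SE TF colocalization
histogram.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomicRegion, RegionSet
from .tables import ExpressionTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_CRITERIA = 2
DEFAULT_COLOC_TOP_N = 100


@dataclass(frozen=True)
class CriterionFlags:
    tf: str
    msat_in_se: bool
    specific_expression: bool
    depmap_dependency: bool

    def n_true(self) -> int:
        return sum([self.msat_in_se, self.specific_expression,
                    self.depmap_dependency])


@dataclass(frozen=True)
class CandidateMTF:
    tf: str
    flags: CriterionFlags
    n_criteria: int
    selected: bool


@dataclass(frozen=True)
class OverlapStats:
    n_dependency_genes: int
    n_se_associated: int

    @property
    def fraction(self) -> float:
        return self.n_se_associated / self.n_dependency_genes


def dependency_filter(table: pd.DataFrame, lineage: str) -> list[str]:
    """Genes of a lineage with a negative dependency T-statistic.

    A negative T-statistic means the dependency is stronger in the tumor
    lineage than in all other models. Deduplicated and sorted.
    """
    rows = table[table["lineage"] == lineage]
    if rows.empty:
        raise ValueError(f"unknown lineage {lineage!r}")
    return sorted(set(rows.loc[rows["t_statistic"] < 0, "gene"]))


def se_dependency_overlap(
    dep_genes: Sequence[str],
    se_assigned_genes: Sequence[str],
) -> OverlapStats:
    """How many dependency genes are the assigned gene of >= 1 SE anywhere."""
    dep = set(dep_genes)
    if not dep:
        raise ValueError("empty dependency gene list")
    assigned = set(se_assigned_genes)
    return OverlapStats(len(dep), len(dep & assigned))


def expression_specificity(
    expr: ExpressionTable,
    tf: str,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    margin: float = 0.0,
) -> bool:
    """Case-specific expression: case median >= control 95th pct + margin."""
    if not case_ids or not control_ids:
        raise ValueError("case and control groups must be non-empty")
    if tf not in expr.values.index:
        raise KeyError(f"gene {tf!r} absent from expression table")
    case = expr.values.loc[tf, list(case_ids)].to_numpy(dtype=float)
    ctrl = expr.values.loc[tf, list(control_ids)].to_numpy(dtype=float)
    return float(np.median(case)) >= float(np.percentile(ctrl, 95)) + margin


def msat_in_se_criterion(tf: str,
                         per_sample_counts: Sequence[float | None]) -> bool:
    """>= 1 mSat peak in the TF's SE in at least half of evaluable samples.

    ``None`` entries mark samples where the TF has no associated SE; they
    are excluded from the denominator. No evaluable sample at all yields
    False (logged).
    """
    evaluable = [c for c in per_sample_counts if c is not None and not (
        isinstance(c, float) and math.isnan(c))]
    if not evaluable:
        logger.warning("TF %s has no sample with an associated SE", tf)
        return False
    n_with = sum(1 for c in evaluable if c >= 1)
    return n_with >= math.ceil(len(evaluable) / 2)


def select_mtfs(flags: Sequence[CriterionFlags],
                min_criteria: int = DEFAULT_MIN_CRITERIA) -> list[CandidateMTF]:
    """Select TFs meeting at least ``min_criteria`` of the three criteria.

    Output order is deterministic: selected TFs first, alphabetical
    within each block.
    """
    out = [
        CandidateMTF(f.tf, f, f.n_true(), f.n_true() >= min_criteria)
        for f in flags
    ]
    out.sort(key=lambda c: (not c.selected, c.tf))
    return out


def colocalization_top_se(
    top_ses: Sequence[GenomicRegion],
    tf_peak_sets: Mapping[str, RegionSet],
) -> tuple[dict[int, int], float]:
    """Distribution of the number of co-bound TFs over the top SEs.

    For each SE, counts TFs with >= 1 peak overlapping it; returns the
    histogram over 0..n_tfs and the fraction of SEs bound by all TFs.
    """
    if not tf_peak_sets:
        raise ValueError("need >= 1 TF peak set")
    n_tfs = len(tf_peak_sets)
    histogram = {k: 0 for k in range(n_tfs + 1)}
    for se in top_ses:
        n_bound = sum(
            1 for peaks in tf_peak_sets.values()
            if any(se.overlaps(p) for p in peaks)
        )
        histogram[n_bound] += 1
    n_total = len(top_ses)
    fraction_all = histogram[n_tfs] / n_total if n_total else 0.0
    return histogram, fraction_all
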