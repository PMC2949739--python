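"""Segment-wise mean r² and Wilcoxon rank-sum comparisons between groups.

Each gene's alignment is cut into equal-length consecutive segments
(default 4); a site pair contributes to a segment only when both sites lie
inside it, giving approximately independent per-segment mean r² values.
Segment means are pooled by gene (across species) or by species (across
genes) and every pair of groups is compared with the two-sided Wilcoxon
rank-sum (Mann-Whitney) test — exact for small tie-free samples, normal
approximation with tie correction otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError
from .ld_pairwise import PairwiseLD


@dataclass(frozen=True)
class SegmentSummary:
    gene_id: str
    species_id: str
    segment_index: int
    start: int  # inclusive column
    end: int  # exclusive column
    n_pairs: int
    mean_r2: float  # nan when no within-segment pair

    def to_dict(self) -> dict:
        return {
            "gene": self.gene_id,
            "species": self.species_id,
            "segment": self.segment_index,
            "start": self.start,
            "end": self.end,
            "n_pairs": self.n_pairs,
            "mean_r2": self.mean_r2,
        }


def segment_bounds(L: int, n_segments: int = 4) -> list[tuple[int, int]]:
    """Consecutive near-equal [start, end) column intervals partitioning [0, L).

    Lengths differ by at most one column; the remainder goes to the
    leftmost segments.
    """
    if L < n_segments:
        raise ConfigurationError(
            f"alignment length {L} shorter than {n_segments} segments"
        )
    base, rem = divmod(L, n_segments)
    bounds = []
    start = 0
    for i in range(n_segments):
        length = base + (1 if i < rem else 0)
        bounds.append((start, start + length))
        start += length
    return bounds


def segment_means(
    pairs: list[PairwiseLD],
    L: int,
    n_segments: int = 4,
    gene_id: str = "",
    species_id: str = "",
) -> list[SegmentSummary]:
    """Mean r² of within-segment site pairs for each segment.

    Pairs straddling a segment boundary are discarded; a segment with no
    within-segment pair gets mean NA.
    """
    bounds = segment_bounds(L, n_segments)
    out = []
    for idx, (start, end) in enumerate(bounds):
        vals = [p.r2 for p in pairs if start <= p.site_i and p.site_j < end]
        out.append(
            SegmentSummary(
                gene_id=gene_id, species_id=species_id, segment_index=idx,
                start=start, end=end, n_pairs=len(vals),
                mean_r2=float(np.mean(vals)) if vals else float("nan"),
            )
        )
    return out


def segments_to_frame(summaries: list[SegmentSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str  # "exact" | "asymptotic"


def wilcoxon_rank_sum(values_a, values_b) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test after NA removal.

    Exact enumeration is used when the combined sample size is <= 20 and
    there are no ties; otherwise the normal approximation with tie and
    continuity correction.  The method actually used is reported.
    """
    a = np.asarray([v for v in values_a if not math.isnan(v)], dtype=float)
    b = np.asarray([v for v in values_b if not math.isnan(v)], dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty after NA removal")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return WilcoxonResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), method=method
    )


@dataclass
class GroupComparison:
    grouping: str  # "by_gene" | "by_species"
    groups: dict[str, list[float]]
    results: pd.DataFrame  # group_a, group_b, n_a, n_b, W, p, method


def _pairwise_tests(grouping: str, groups: dict[str, list[float]]) -> GroupComparison:
    rows = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        a = [v for v in groups[ga] if not math.isnan(v)]
        b = [v for v in groups[gb] if not math.isnan(v)]
        if not a or not b:
            rows.append(
                {"group_a": ga, "group_b": gb, "n_a": len(a), "n_b": len(b),
                 "W": float("nan"), "p": float("nan"), "method": "untestable"}
            )
            continue
        res = wilcoxon_rank_sum(a, b)
        rows.append(
            {"group_a": ga, "group_b": gb, "n_a": len(a), "n_b": len(b),
             "W": res.statistic, "p": res.p_value, "method": res.method}
        )
    frame = pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "W", "p", "method"]
    )
    return GroupComparison(grouping=grouping, groups=groups, results=frame)


def compare_groups(
    segment_summaries: list[SegmentSummary], grouping: str = "by_gene"
) -> GroupComparison:
    """Pairwise Wilcoxon tests on pooled per-segment mean r² values.

    ``by_gene`` pools each gene's segment means across species (up to
    n_segments x n_species values per list); ``by_species`` pools across
    genes.  NA segments are dropped, never imputed.
    """
    key = {"by_gene": lambda s: s.gene_id, "by_species": lambda s: s.species_id}
    if grouping not in key:
        raise ConfigurationError(f"grouping must be by_gene or by_species, got {grouping!r}")
    groups: dict[str, list[float]] = {}
    for s in segment_summaries:
        groups.setdefault(key[grouping](s), []).append(s.mean_r2)
    return _pairwise_tests(grouping, groups)


def compare_group_means(
    dataset_means: pd.DataFrame, grouping: str = "by_gene"
) -> GroupComparison:
    """Coarser variant using one whole-sequence mean r² per gene x species.

    ``dataset_means`` must have columns ``gene``, ``species``, ``mean_r2``;
    each group's list then holds one value per dataset (e.g. one per
    species when grouping by gene).
    """
    col = {"by_gene": "gene", "by_species": "species"}
    if grouping not in col:
        raise ConfigurationError(f"grouping must be by_gene or by_species, got {grouping!r}")
    groups: dict[str, list[float]] = {}
    for _, row in dataset_means.iterrows():
        groups.setdefault(str(row[col[grouping]]), []).append(float(row["mean_r2"]))
    return _pairwise_tests(grouping, groups)
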