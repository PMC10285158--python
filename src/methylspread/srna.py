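"""sRNA-cluster merging, cross-stage consensus, and block-overlap analysis.

Small-RNA-producing intervals (21-nt or 24-nt size classes, identified
upstream by a clustering tool) are merged per stage when they lie within
75 bp of each other — inclusive, unlike the strict <40 bp rule for
methylation blocks.  A cross-stage consensus keeps bases covered in at least
five of the eight sRNA stages.  Consensus CHH methylation blocks are then
partitioned by whether they share at least 1 bp with any consensus cluster,
separating RdDM-associated spreading loci from sRNA-independent ones.

The sRNA stage axis (eight stages, from public embryo sRNA data) is kept
independent of the five methylome stages; no alignment between the two
stagings is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import merge_intervals, overlaps_any, support_intervals

SIZE_CLASSES = ("21nt", "24nt")


@dataclass(frozen=True)
class SRNACluster:
    """A stage-tagged sRNA-producing interval."""

    chrom: str
    start: int
    end: int
    stage: str
    size_class: str = "24nt"

    def __post_init__(self):
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"size_class must be one of {SIZE_CLASSES}")


def merge_srna_clusters(clusters: pd.DataFrame, max_gap: int = 75
                        ) -> pd.DataFrame:
    """Merge one stage's clusters lying within *max_gap* bp (inclusive).

    Clusters whose end-to-start gap is ≤ *max_gap* merge transitively; a gap
    of exactly *max_gap* merges, one base more does not.
    """
    merged = merge_intervals(clusters, max_gap=max_gap, inclusive=True)
    merged = merged.rename(columns={"n_intervals": "n_clusters"})
    merged.attrs["max_gap"] = max_gap
    return merged


def consensus_clusters(per_stage_merged: Sequence[pd.DataFrame],
                       min_stages: int = 5, max_gap: int = 75,
                       resolution: str = "base") -> pd.DataFrame:
    """Consensus sRNA clusters common to ≥ *min_stages* of the stages.

    ``resolution="base"`` (default) keeps individual bases covered by a
    merged cluster in at least *min_stages* stages, then assembles intervals
    with the inclusive ≤*max_gap* rule.  ``resolution="cluster"`` instead
    keeps whole candidate regions (the union of all stages' clusters, merged)
    that are hit by ≥1 cluster in at least *min_stages* stages.
    """
    per_stage_merged = list(per_stage_merged)
    if min_stages > len(per_stage_merged):
        raise ValueError(
            f"min_stages={min_stages} exceeds number of stages "
            f"({len(per_stage_merged)})"
        )
    if resolution == "base":
        support = support_intervals(per_stage_merged, min_stages)
        return merge_intervals(support, max_gap=max_gap, inclusive=True) \
            .rename(columns={"n_intervals": "n_segments"})
    if resolution == "cluster":
        nonempty = [s for s in per_stage_merged if len(s)]
        if not nonempty:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        candidates = merge_intervals(
            pd.concat(nonempty, ignore_index=True),
            max_gap=max_gap, inclusive=True,
        ).drop(columns="n_intervals")
        hits = np.zeros(len(candidates), dtype=np.int64)
        for stage_df in per_stage_merged:
            hits += overlaps_any(candidates, stage_df)
        return candidates[hits >= min_stages].reset_index(drop=True)
    raise ValueError(f"unknown resolution {resolution!r}")


def classify_block_overlap(consensus_blocks: pd.DataFrame,
                           clusters: pd.DataFrame
                           ) -> dict[str, pd.DataFrame]:
    """Partition consensus blocks by ≥1 bp overlap with sRNA clusters.

    Returns ``{"overlapping": ..., "non_overlapping": ...}``; the two groups
    partition the input (no block is in both, none is dropped).
    """
    hit = overlaps_any(consensus_blocks, clusters)
    return {
        "overlapping": consensus_blocks[hit].reset_index(drop=True),
        "non_overlapping": consensus_blocks[~hit].reset_index(drop=True),
    }


def overlap_group_stats(groups: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Length summaries (mean, population SD, n) for overlap groups."""
    rows = []
    for name, df in groups.items():
        if len(df) == 0:
            rows.append({"group": name, "mean_length": np.nan,
                         "sd_length": np.nan, "n": 0})
            continue
        lengths = (df["end"] - df["start"]).to_numpy(dtype=float)
        rows.append(
            {
                "group": name,
                "mean_length": float(lengths.mean()),
                "sd_length": float(lengths.std(ddof=0)),
                "n": int(len(lengths)),
            }
        )
    return pd.DataFrame(rows, columns=["group", "mean_length", "sd_length", "n"])
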