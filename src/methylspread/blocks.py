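"""The CHH-spreading statistic: methylated blocks and their growth.

A *methylated block* is a maximal run of small (10 bp) methylation windows
whose level strictly exceeds a cutoff (5, 10 or 15%), merged transitively
whenever consecutive windows lie strictly closer than 40 bp apart.  Computed
per developmental stage, the mean block length traces the spatial spreading
of CHH methylation as the embryo matures.

The window grid and coverage eligibility are fixed across stages; cutoff
passing and merging are evaluated per stage, which is what lets the
per-stage block length grow.  A cross-stage consensus (base-resolution
support in ≥3 of 5 stages at the 15% cutoff) defines the stable spreading
loci used for sRNA-overlap analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import merge_intervals, support_intervals
from .windows import windowed_levels


@dataclass(frozen=True)
class BlockLengthSummary:
    stage: str
    mean_length: float
    sd_length: float
    n_blocks: int


def qualifying_windows(records: pd.DataFrame, cutoff: float,
                       window_size: int = 10, min_sites: int = 1,
                       min_reads: int = 5, context: str = "CHH",
                       chrom_sizes=None) -> pd.DataFrame:
    """10 bp windows whose methylation level strictly exceeds *cutoff*.

    Windows are computed as in :func:`methylspread.windows.windowed_levels`
    (≥ *min_sites* cytosines at depth ≥ *min_reads*); a window whose level
    equals the cutoff exactly is excluded ("above" is strict).
    """
    if not (0 <= cutoff < 1):
        raise ValueError(f"cutoff must be in [0, 1), got {cutoff}")
    win = windowed_levels(
        records, window_size, min_cytosines=min_sites,
        min_reads_per_cytosine=min_reads, context=context,
        chrom_sizes=chrom_sizes,
    )
    out = win[win["level"] > cutoff].reset_index(drop=True)
    out.attrs.update(win.attrs)
    out.attrs["cutoff"] = cutoff
    return out


def merge_blocks(windows: pd.DataFrame, max_gap: int = 40) -> pd.DataFrame:
    """Merge qualifying windows into blocks (gap strictly < *max_gap*).

    The gap is measured end-to-start in half-open coordinates, so adjacent
    windows (gap 0) always merge; windows exactly *max_gap* apart do not.
    Returns chrom/start/end with ``n_windows`` per block.
    """
    merged = merge_intervals(windows, max_gap=max_gap, inclusive=False)
    merged = merged.rename(columns={"n_intervals": "n_windows"})
    merged.attrs["max_gap"] = max_gap
    if "cutoff" in windows.attrs:
        merged.attrs["cutoff"] = windows.attrs["cutoff"]
    return merged


def block_length_stats(blocks_by_stage: Mapping[str, pd.DataFrame]
                       ) -> pd.DataFrame:
    """Mean, population SD, and count of block lengths per stage.

    Stage order follows the mapping order; stages with zero blocks are
    omitted with a warning.
    """
    rows = []
    for stage, blocks in blocks_by_stage.items():
        if len(blocks) == 0:
            warnings.warn(f"stage {stage!r} has no blocks; summary omitted")
            continue
        lengths = (blocks["end"] - blocks["start"]).to_numpy(dtype=float)
        rows.append(
            {
                "stage": stage,
                "mean_length": float(lengths.mean()),
                "sd_length": float(lengths.std(ddof=0)),
                "n_blocks": int(len(lengths)),
            }
        )
    return pd.DataFrame(rows, columns=["stage", "mean_length", "sd_length",
                                       "n_blocks"])


def consensus_chh_blocks(per_stage_windows: Sequence[pd.DataFrame],
                         min_stages: int = 3, max_gap: int = 40
                         ) -> pd.DataFrame:
    """Consensus blocks: bases qualifying in ≥ *min_stages* stages, merged.

    *per_stage_windows* are the per-stage qualifying-window tables (already
    cutoff-filtered, typically at 15%).  Bases covered by a qualifying window
    in at least *min_stages* stages are retained and assembled into blocks
    with the same strict <*max_gap* rule as per-stage merging.
    """
    support = support_intervals(list(per_stage_windows), min_stages)
    return merge_intervals(support, max_gap=max_gap, inclusive=False) \
        .rename(columns={"n_intervals": "n_segments"})


def stage_change_test(values_a, values_b) -> float:
    """Two-sided Welch two-sample t-test p-value between adjacent stages.

    Used to compare per-locus values (e.g. block lengths) of one
    developmental stage against the prior stage.  Requires n ≥ 2 per sample.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
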