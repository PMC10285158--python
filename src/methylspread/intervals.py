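"""Interval arithmetic shared by the block, sRNA, and classification modules.

All intervals are 0-based half-open.  Three primitives cover everything the
pipeline needs:

* :func:`merge_intervals` — transitive gap-merging with either a strict
  (``gap < max_gap``) or inclusive (``gap ≤ max_gap``) rule.  The gap between
  two intervals is measured end-to-start, so adjacent half-open intervals
  have gap 0 and always merge.
* :func:`support_intervals` — base-resolution consensus: the maximal runs of
  positions covered in at least ``min_support`` of the given interval sets.
* :func:`overlaps_any` — per-query boolean ≥1 bp overlap against a subject
  set (bedtools ``intersect -wa``-style semantics).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def _as_interval_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval table lacks columns {missing}")
    return df


def _empty_merged() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "n_intervals": pd.Series(dtype=np.int64),
        }
    )


def merge_intervals(df: pd.DataFrame, max_gap: int = 0,
                    inclusive: bool = False) -> pd.DataFrame:
    """Merge intervals whose end-to-start gap is below (or at) *max_gap*.

    Merging is transitive and per chromosome.  With ``inclusive=False`` two
    intervals merge iff ``next.start - current.end < max_gap``; with
    ``inclusive=True`` iff ``≤ max_gap``.  Overlapping intervals (negative
    gap) always merge.  Returns chrom/start/end plus ``n_intervals``, the
    number of input intervals absorbed into each merged interval.
    """
    _as_interval_frame(df)
    if len(df) == 0:
        return _empty_merged()
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)

    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    out_n: list[int] = []
    cur_chrom = chroms[0]
    cur_start = starts[0]
    cur_end = ends[0]
    cur_n = 1
    for i in range(1, len(df)):
        gap = starts[i] - cur_end
        same = chroms[i] == cur_chrom
        joined = (gap <= max_gap) if inclusive else (gap < max_gap)
        if same and joined:
            cur_end = max(cur_end, ends[i])
            cur_n += 1
        else:
            out_chrom.append(cur_chrom)
            out_start.append(cur_start)
            out_end.append(cur_end)
            out_n.append(cur_n)
            cur_chrom, cur_start, cur_end, cur_n = (
                chroms[i], starts[i], ends[i], 1,
            )
    out_chrom.append(cur_chrom)
    out_start.append(cur_start)
    out_end.append(cur_end)
    out_n.append(cur_n)
    return pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": np.asarray(out_start, dtype=np.int64),
            "end": np.asarray(out_end, dtype=np.int64),
            "n_intervals": np.asarray(out_n, dtype=np.int64),
        }
    )


def union_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: overlapping or book-ended intervals coalesced."""
    return merge_intervals(df, max_gap=0, inclusive=True)


def support_intervals(interval_sets: Sequence[pd.DataFrame],
                      min_support: int) -> pd.DataFrame:
    """Maximal runs of bases covered by ≥ *min_support* of the interval sets.

    Each set contributes at most once per base (its intervals are unioned
    first), so *min_support* counts distinct sets — e.g. developmental stages
    — not raw intervals.
    """
    if min_support > len(interval_sets):
        raise ValueError(
            f"min_support={min_support} exceeds the number of interval sets "
            f"({len(interval_sets)})"
        )
    if min_support < 1:
        raise ValueError("min_support must be ≥ 1")
    unions = [union_intervals(s) for s in interval_sets if len(s)]
    if not unions:
        return _empty_merged().drop(columns="n_intervals")
    events = pd.concat(
        [
            pd.DataFrame(
                {
                    "chrom": pd.concat([u["chrom"], u["chrom"]]),
                    "pos": pd.concat([u["start"], u["end"]]),
                    "delta": np.r_[
                        np.ones(len(u), dtype=np.int64),
                        -np.ones(len(u), dtype=np.int64),
                    ],
                }
            )
            for u in unions
        ],
        ignore_index=True,
    )
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, grp in events.groupby("chrom", sort=True):
        agg = grp.groupby("pos")["delta"].sum().sort_index()
        pos = agg.index.to_numpy(dtype=np.int64)
        cov = np.cumsum(agg.to_numpy())
        covered = cov >= min_support
        run_start = None
        for i, p in enumerate(pos):
            if covered[i] and run_start is None:
                run_start = p
            elif not covered[i] and run_start is not None:
                out_chrom.append(chrom)
                out_start.append(run_start)
                out_end.append(int(p))
                run_start = None
        # coverage always returns to zero at the last breakpoint
    df = pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": np.asarray(out_start, dtype=np.int64),
            "end": np.asarray(out_end, dtype=np.int64),
        }
    )
    # adjacent runs can arise from breakpoints interior to a covered region
    if len(df):
        df = union_intervals(df).drop(columns="n_intervals")
    return df


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each query interval share ≥1 bp with any subject?"""
    _as_interval_frame(query)
    _as_interval_frame(subject)
    result = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return result
    merged = union_intervals(subject)
    for chrom, grp in merged.groupby("chrom"):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        s = grp["start"].to_numpy(dtype=np.int64)
        e = grp["end"].to_numpy(dtype=np.int64)
        qs = query.loc[mask, "start"].to_numpy(dtype=np.int64)
        qe = query.loc[mask, "end"].to_numpy(dtype=np.int64)
        # last subject starting before the query end; overlap iff it extends
        # past the query start (subjects are disjoint and sorted)
        idx = np.searchsorted(s, qe, side="left") - 1
        hit = (idx >= 0) & (e[np.clip(idx, 0, None)] > qs)
        result[np.flatnonzero(mask)] = hit
    return result
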