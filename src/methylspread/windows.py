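"""Coverage-filtered fixed-width windowed methylation levels.

Whole-genome bisulfite calls are summarized in non-overlapping windows on a
grid anchored at coordinate 0 of each chromosome.  A window is emitted only
if it contains enough cytosines of the requested context, each with enough
aligned reads; its level is the read-weighted mean
``Σ meth / (Σ meth + Σ unmeth)`` over the qualifying cytosines.  Both
strands' cytosines of a context contribute to the same window.

Two standard parameterizations are used for embryo methylomes: 50 bp windows
with ≥3 cytosines at depth ≥5 for feature-level dynamics, and 5 kb windows
with strictly more than 10 cytosines at depth ≥5 for chromosome-scale maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

WINDOW_COLUMNS = [
    "chrom", "start", "end", "context", "n_cytosines", "total_reads", "level",
]


@dataclass(frozen=True)
class MethylationWindow:
    """One window's pooled methylation summary for a single stage."""

    chrom: str
    start: int
    end: int
    context: str
    n_cytosines: int
    total_reads: int
    level: float


def _empty_windows(window_size: int) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "context": pd.Series(dtype=str),
            "n_cytosines": pd.Series(dtype=np.int64),
            "total_reads": pd.Series(dtype=np.int64),
            "level": pd.Series(dtype=float),
        }
    )
    df.attrs["window_size"] = window_size
    return df


def windowed_levels(records: pd.DataFrame, window_size: int,
                    min_cytosines: int = 3, min_reads_per_cytosine: int = 5,
                    context: str = "CHH",
                    chrom_sizes: Mapping[str, int] | None = None,
                    strict_min_cytosines: bool = False) -> pd.DataFrame:
    """Windowed methylation levels for one stage and one context.

    A window qualifies when it holds ≥ *min_cytosines* cytosines of
    *context*, each with total depth ≥ *min_reads_per_cytosine* (with
    ``strict_min_cytosines=True`` the count must strictly exceed
    *min_cytosines*).  The window grid starts at 0; the trailing partial
    window of a chromosome is retained if it passes the filters, and window
    ends are clipped to *chrom_sizes* when provided.

    Returns a window table sorted by chrom/start, with the grid size recorded
    in ``df.attrs["window_size"]``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    sub = records[records["context"] == context]
    depth = sub["meth"] + sub["unmeth"]
    sub = sub[depth >= min_reads_per_cytosine]
    if len(sub) == 0:
        return _empty_windows(window_size)
    widx = (sub["pos"].to_numpy(dtype=np.int64) - 1) // window_size
    grouped = (
        pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "widx": widx,
                "meth": sub["meth"].to_numpy(dtype=np.int64),
                "total": (sub["meth"] + sub["unmeth"]).to_numpy(dtype=np.int64),
            }
        )
        .groupby(["chrom", "widx"], sort=True)
        .agg(n_cytosines=("meth", "size"), meth=("meth", "sum"),
             total=("total", "sum"))
        .reset_index()
    )
    if strict_min_cytosines:
        grouped = grouped[grouped["n_cytosines"] > min_cytosines]
    else:
        grouped = grouped[grouped["n_cytosines"] >= min_cytosines]
    start = grouped["widx"].to_numpy(dtype=np.int64) * window_size
    end = start + window_size
    if chrom_sizes is not None:
        limits = grouped["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, limits.astype(np.int64))
    out = pd.DataFrame(
        {
            "chrom": grouped["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "context": context,
            "n_cytosines": grouped["n_cytosines"].to_numpy(dtype=np.int64),
            "total_reads": grouped["total"].to_numpy(dtype=np.int64),
            "level": grouped["meth"].to_numpy(dtype=float)
            / grouped["total"].to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    out.attrs["window_size"] = window_size
    return out


def shared_windows(per_stage_windows: Mapping[str, pd.DataFrame] |
                   Sequence[tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    """Windows present in every stage, with per-stage levels in stage order.

    Keeps exactly the ``(chrom, start, context)`` keys emitted in all stages
    and attaches one ``level_<stage>`` column per stage.  All inputs must
    share the same window grid (as recorded by :func:`windowed_levels`).
    """
    items = list(per_stage_windows.items()) \
        if isinstance(per_stage_windows, Mapping) else list(per_stage_windows)
    if not items:
        raise ValueError("no stages given")
    sizes = {df.attrs.get("window_size") for _, df in items}
    if len(sizes) != 1:
        raise ValueError(f"mismatched window grids across stages: {sizes}")
    key = ["chrom", "start", "context"]
    merged: pd.DataFrame | None = None
    for label, df in items:
        cols = df[key + ["end", "level"]].rename(
            columns={"level": f"level_{label}"}
        )
        if merged is None:
            merged = cols
        else:
            merged = merged.merge(cols.drop(columns="end"), on=key, how="inner")
    assert merged is not None
    merged.attrs["window_size"] = sizes.pop()
    merged.attrs["stages"] = [label for label, _ in items]
    return merged.sort_values(["chrom", "start"]).reset_index(drop=True)


def global_window_map(records: pd.DataFrame, window_size: int = 5000,
                      min_cytosines: int = 10,
                      min_reads_per_cytosine: int = 5,
                      context: str | None = None,
                      chrom_sizes: Mapping[str, int] | None = None,
                      ) -> pd.DataFrame:
    """Chromosome-scale window map (5 kb grid, strictly >10 cytosines).

    The cytosine-count filter is strict — a window with exactly
    *min_cytosines* qualifying cytosines is excluded.  With ``context=None``
    all three contexts are computed and concatenated.
    """
    contexts = ("CG", "CHG", "CHH") if context is None else (context,)
    parts = [
        windowed_levels(
            records, window_size, min_cytosines=min_cytosines,
            min_reads_per_cytosine=min_reads_per_cytosine, context=ctx,
            chrom_sizes=chrom_sizes, strict_min_cytosines=True,
        )
        for ctx in contexts
    ]
    out = pd.concat(parts, ignore_index=True)
    out.attrs["window_size"] = window_size
    return out
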