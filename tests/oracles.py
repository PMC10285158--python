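"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — per-base arrays, all-pairs loops,
interval trees — and shares no code with the package's own interval sweeps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


def brute_merge(intervals: pd.DataFrame, max_gap: int,
                inclusive: bool) -> list[tuple[str, int, int]]:
    """Gap-merging by repeated pairwise joining until a fixed point."""
    items = [
        (r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in intervals.iterrows()
    ]
    changed = True
    while changed:
        changed = False
        out: list[tuple[str, int, int]] = []
        for chrom, s, e in sorted(items):
            merged = False
            for i, (c2, s2, e2) in enumerate(out):
                if c2 != chrom:
                    continue
                gap = max(s, s2) - min(e, e2)
                joined = gap <= max_gap if inclusive else gap < max_gap
                if joined or (s < e2 and s2 < e):
                    out[i] = (c2, min(s, s2), max(e, e2))
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append((chrom, s, e))
        items = out
    return sorted(items)


def brute_support(interval_sets, min_support: int,
                  span: int = 1_000_000) -> list[tuple[str, int, int]]:
    """Per-base coverage counting over explicit arrays."""
    chroms = sorted(
        {c for df in interval_sets for c in df["chrom"].unique()}
    )
    out = []
    for chrom in chroms:
        cov = np.zeros(span, dtype=np.int64)
        for df in interval_sets:
            mask = np.zeros(span, dtype=bool)
            sub = df[df["chrom"] == chrom]
            for _, r in sub.iterrows():
                mask[int(r["start"]):int(r["end"])] = True
            cov += mask
        keep = cov >= min_support
        diff = np.diff(np.r_[False, keep, False].astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        out += [(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    return sorted(out)


def tree_overlaps(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Per-query ≥1 bp overlap flags via an interval tree."""
    trees: dict[str, IntervalTree] = {}
    for _, r in subject.iterrows():
        trees.setdefault(r["chrom"], IntervalTree()).addi(
            int(r["start"]), int(r["end"])
        )
    return np.array(
        [
            bool(trees.get(r["chrom"], IntervalTree())
                 .overlap(int(r["start"]), int(r["end"])))
            for _, r in query.iterrows()
        ],
        dtype=bool,
    )


def brute_windows(records: pd.DataFrame, window_size: int, min_cytosines: int,
                  min_reads: int, context: str,
                  strict: bool = False) -> dict[tuple[str, int], tuple[int, float]]:
    """Per-window loop: (chrom, start) -> (n_cytosines, level)."""
    sites = [
        r for _, r in records.iterrows()
        if r["context"] == context and r["meth"] + r["unmeth"] >= min_reads
    ]
    buckets: dict[tuple[str, int], list] = {}
    for r in sites:
        start = ((int(r["pos"]) - 1) // window_size) * window_size
        buckets.setdefault((r["chrom"], start), []).append(r)
    out = {}
    for key, rows in buckets.items():
        n = len(rows)
        ok = n > min_cytosines if strict else n >= min_cytosines
        if not ok:
            continue
        meth = sum(int(r["meth"]) for r in rows)
        total = sum(int(r["meth"]) + int(r["unmeth"]) for r in rows)
        out[key] = (n, meth / total)
    return out


def brute_assign(tes: pd.DataFrame, dmrs_by_class) -> list[str]:
    """All-pairs TE→DMR class assignment."""
    labels = []
    for _, te in tes.iterrows():
        hit = set()
        for cls, dmrs in dmrs_by_class.items():
            for _, d in dmrs.iterrows():
                if (te["chrom"] == d["chrom"] and te["start"] < d["end"]
                        and d["start"] < te["end"]):
                    hit.add(cls)
        if len(hit) == 0:
            labels.append("unassigned")
        elif len(hit) == 1:
            labels.append(hit.pop())
        else:
            labels.append("multi-class")
    return labels


def brute_metaprofile(records: pd.DataFrame, features: pd.DataFrame,
                      flank_bp: int, n_bins_body: int, n_bins_flank: int,
                      context: str, min_reads: int) -> np.ndarray:
    """Per-site loop over every feature, read-weighted bin levels."""
    n_bins = 2 * n_bins_flank + n_bins_body
    meth = np.zeros(n_bins)
    total = np.zeros(n_bins)
    sites = records[
        (records["context"] == context)
        & (records["meth"] + records["unmeth"] >= min_reads)
    ]
    for _, f in features.iterrows():
        start, end = int(f["start"]), int(f["end"])
        strand = f.get("strand", "+")
        for _, s in sites[sites["chrom"] == f["chrom"]].iterrows():
            p = int(s["pos"]) - 1
            if p < start - flank_bp or p >= end + flank_bp:
                continue
            if p < start:
                b = int((p - (start - flank_bp))
                        // (flank_bp / n_bins_flank))
            elif p >= end:
                b = (n_bins_flank + n_bins_body
                     + int((p - end) // (flank_bp / n_bins_flank)))
            else:
                b = n_bins_flank + (p - start) * n_bins_body // (end - start)
            if strand == "-":
                b = n_bins - 1 - b
            meth[b] += int(s["meth"])
            total[b] += int(s["meth"]) + int(s["unmeth"])
    with np.errstate(invalid="ignore"):
        return np.where(total > 0, meth / total, np.nan)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_context_counts(seq: str) -> tuple[int, int, int]:
    """Pure-python context counting (CG/CHG forward, CHH both strands)."""
    seq = seq.upper()
    rc = "".join(_COMPLEMENT[b] for b in reversed(seq))
    H = set("ACT")
    n_cg = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CG")
    n_chg = sum(
        1 for i in range(len(seq) - 2)
        if seq[i] == "C" and seq[i + 1] in H and seq[i + 2] == "G"
    )

    def chh(s):
        return sum(
            1 for i in range(len(s) - 2)
            if s[i] == "C" and s[i + 1] in H and s[i + 2] in H
        )

    return n_cg, n_chg, chh(seq) + chh(rc)
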