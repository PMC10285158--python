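"""Exclusive assignment of TEs to CHH-pathway DMR classes and summaries.

Transposable elements are allocated to three differentially-methylated-region
(DMR) classes by pathway dependency: cCMT2 (CMT2-dependent in both leaf and
embryo), cRdDM (RdDM-dependent in both), and eRdDM (embryo-specific RdDM
targets).  A TE overlapping (≥1 bp, bedtools ``intersect -wa`` semantics)
DMRs of exactly one class takes that class; a TE hitting two or more classes
is flagged ``multi-class`` and removed from all class-level summaries; a TE
hitting none is ``unassigned``.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import overlaps_any

DMR_CLASSES = ("cCMT2", "cRdDM", "eRdDM")
SUPERFAMILIES = ("Copia", "Gypsy", "Helitron", "MuDR", "En-Spm", "LINE",
                 "SINE", "Remainder")
MULTI_CLASS = "multi-class"
UNASSIGNED = "unassigned"


def assign_dmr_class(tes: pd.DataFrame,
                     dmrs_by_class: Mapping[str, pd.DataFrame]
                     ) -> pd.DataFrame:
    """Assign each TE to exactly one DMR class, or flag it for exclusion.

    *tes* needs chrom/start/end (``te_id``/``superfamily`` are carried
    through when present).  *dmrs_by_class* maps class labels — a subset of
    ``{"cCMT2", "cRdDM", "eRdDM"}`` — to DMR interval tables; an unknown
    label raises.  Multiple same-class DMRs hitting one TE count once.

    Returns the TE table with a ``dmr_class`` column whose values partition
    the input into the three classes plus ``multi-class`` and ``unassigned``.
    """
    unknown = set(dmrs_by_class) - set(DMR_CLASSES)
    if unknown:
        raise ValueError(f"unknown DMR class label(s): {sorted(unknown)}")
    out = tes.copy().reset_index(drop=True)
    n_hits = np.zeros(len(out), dtype=np.int64)
    label = np.full(len(out), UNASSIGNED, dtype=object)
    for cls in DMR_CLASSES:  # fixed order: symmetric in input order
        if cls not in dmrs_by_class:
            continue
        hit = overlaps_any(out, dmrs_by_class[cls])
        label[hit & (n_hits == 0)] = cls
        n_hits += hit
    label[n_hits > 1] = MULTI_CLASS
    out["dmr_class"] = label
    return out


def classified_only(classified: pd.DataFrame) -> pd.DataFrame:
    """Drop multi-class and unassigned TEs (the exclusive class sets)."""
    return classified[classified["dmr_class"].isin(DMR_CLASSES)] \
        .reset_index(drop=True)


def class_length_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean, population SD, and count of TE length (bp).

    Classes are reported in the fixed order cCMT2, cRdDM, eRdDM; an empty
    class is omitted with a warning.
    """
    rows = []
    for cls in DMR_CLASSES:
        sub = classified[classified["dmr_class"] == cls]
        if len(sub) == 0:
            warnings.warn(f"class {cls} has no TEs; summary omitted")
            continue
        lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        rows.append(
            {
                "dmr_class": cls,
                "mean_length": float(lengths.mean()),
                "sd_length": float(lengths.std(ddof=0)),
                "n": int(len(lengths)),
            }
        )
    return pd.DataFrame(rows, columns=["dmr_class", "mean_length",
                                       "sd_length", "n"])


def superfamily_composition(classified: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each superfamily within each DMR class (sums to 1).

    Superfamilies outside the seven named ones are pooled as ``Remainder``.
    Empty classes produce no rows.
    """
    if "superfamily" not in classified.columns:
        raise ValueError("TE table lacks a 'superfamily' column")
    sub = classified_only(classified).copy()
    known = set(SUPERFAMILIES) - {"Remainder"}
    sub["superfamily"] = [
        sf if sf in known else "Remainder" for sf in sub["superfamily"]
    ]
    rows = []
    for cls in DMR_CLASSES:
        cls_tes = sub[sub["dmr_class"] == cls]
        if len(cls_tes) == 0:
            continue
        counts = cls_tes["superfamily"].value_counts()
        for sf in SUPERFAMILIES:
            rows.append(
                {
                    "dmr_class": cls,
                    "superfamily": sf,
                    "fraction": counts.get(sf, 0) / len(cls_tes),
                    "n": int(counts.get(sf, 0)),
                }
            )
    return pd.DataFrame(rows, columns=["dmr_class", "superfamily",
                                       "fraction", "n"])


def positional_distribution(intervals: pd.DataFrame, chrom_length: int,
                            n_bins: int, by: str = "midpoint") -> np.ndarray:
    """Fraction of intervals per equal-width chromosomal bin.

    Intervals (all on one chromosome) are assigned to the bin containing
    their midpoint (``by="midpoint"``, default) or start (``by="start"``);
    a midpoint exactly on a bin boundary falls in the right-hand bin
    (half-open binning).  Fractions sum to 1 for non-empty input.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be ≥ 1")
    if len(intervals) == 0:
        return np.zeros(n_bins)
    starts = intervals["start"].to_numpy(dtype=np.int64)
    ends = intervals["end"].to_numpy(dtype=np.int64)
    if (starts < 0).any() or (ends > chrom_length).any():
        bad = intervals.iloc[int(np.argmax((starts < 0) | (ends > chrom_length)))]
        raise ValueError(
            f"interval {bad['chrom']}:{bad['start']}-{bad['end']} lies "
            f"outside chromosome of length {chrom_length}"
        )
    if by == "midpoint":
        anchor = (starts + ends) / 2.0
    elif by == "start":
        anchor = starts.astype(float)
    else:
        raise ValueError(f"unknown binning anchor {by!r}")
    idx = np.minimum((anchor * n_bins // chrom_length).astype(np.int64),
                     n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return counts / counts.sum()
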