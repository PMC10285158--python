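"""Methylation metaprofiles over features and per-TE mean levels.

A metaprofile averages per-cytosine methylation over a feature set: each
feature body is scaled to a fixed number of bins, flanking regions get
fixed-width bins, and minus-strand features are reversed so that profiles
read 5'→3'.  Bin levels are read-weighted (Σ meth / Σ total over all sites of
all features mapping to the bin).

Per-TE methylation uses the opposite convention: the *unweighted* mean of the
per-site methylation fractions over covered cytosines inside the TE, which
makes the statistic independent of sequencing-depth variation between sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MetaProfile:
    """Binned mean methylation over a feature set with flanks."""

    context: str
    flank_bp: int
    n_bins_body: int
    n_bins_flank: int
    levels: np.ndarray
    meth_sums: np.ndarray = field(repr=False, default=None)
    total_sums: np.ndarray = field(repr=False, default=None)

    @property
    def n_bins(self) -> int:
        return 2 * self.n_bins_flank + self.n_bins_body

    def to_frame(self) -> pd.DataFrame:
        zone = (["upstream"] * self.n_bins_flank
                + ["body"] * self.n_bins_body
                + ["downstream"] * self.n_bins_flank)
        return pd.DataFrame(
            {"bin": np.arange(self.n_bins), "zone": zone,
             "level": self.levels}
        )


@dataclass(frozen=True)
class TELevel:
    """One TE's mean per-site methylation (undefined when no covered sites)."""

    te_id: str
    context: str
    mean_site_level: float
    n_sites: int

    @property
    def defined(self) -> bool:
        return self.n_sites > 0


def _site_arrays(records: pd.DataFrame, context: str, min_reads: int
                 ) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome sorted (pos0, meth, total) arrays of qualifying sites."""
    sub = records[records["context"] == context]
    total = (sub["meth"] + sub["unmeth"]).to_numpy(dtype=np.int64)
    sub = sub[total >= min_reads]
    out = {}
    for chrom, grp in sub.groupby("chrom"):
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1
        order = np.argsort(pos0, kind="mergesort")
        out[chrom] = (
            pos0[order],
            grp["meth"].to_numpy(dtype=np.int64)[order],
            (grp["meth"] + grp["unmeth"]).to_numpy(dtype=np.int64)[order],
        )
    return out


def feature_metaprofile(records: pd.DataFrame, features: pd.DataFrame,
                        flank_bp: int = 1500, n_bins_body: int = 60,
                        n_bins_flank: int = 30, context: str = "CG",
                        min_reads: int = 5) -> MetaProfile:
    """Read-weighted metaprofile of *context* methylation over *features*.

    Features (chrom/start/end, optional strand) are scaled to *n_bins_body*
    body bins with *n_bins_flank* fixed-width bins per flank; minus-strand
    features contribute in 5'→3' orientation.  Flanks are clipped at
    position 0 (and effectively at chromosome ends, where no sites exist).
    Sites with depth < *min_reads* are ignored.  Raises on an empty feature
    set.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    if flank_bp < 0 or n_bins_body < 1 or n_bins_flank < 0:
        raise ValueError("invalid binning parameters")
    sites = _site_arrays(records, context, min_reads)
    n_bins = 2 * n_bins_flank + n_bins_body
    meth_sums = np.zeros(n_bins, dtype=np.float64)
    total_sums = np.zeros(n_bins, dtype=np.float64)
    flank_bin_w = flank_bp / n_bins_flank if n_bins_flank else None

    for f in features.itertuples(index=False):
        if f.chrom not in sites:
            continue
        pos, meth, total = sites[f.chrom]
        start, end = int(f.start), int(f.end)
        strand = getattr(f, "strand", "+")
        lo = np.searchsorted(pos, start - flank_bp, side="left")
        hi = np.searchsorted(pos, end + flank_bp, side="left")
        if lo == hi:
            continue
        p = pos[lo:hi]
        m = meth[lo:hi]
        t = total[lo:hi]
        bins = np.empty(len(p), dtype=np.int64)
        up = p < start
        down = p >= end
        body = ~up & ~down
        if n_bins_flank:
            bins[up] = (p[up] - (start - flank_bp)) // flank_bin_w
            bins[down] = (n_bins_flank + n_bins_body
                          + (p[down] - end) // flank_bin_w)
        elif up.any() or down.any():
            keep = body
            p, m, t, bins = p[keep], m[keep], t[keep], bins[keep]
            body = np.ones(len(p), dtype=bool)
        bins[body] = n_bins_flank + (p[body] - start) * n_bins_body // (end - start)
        if strand == "-":
            bins = n_bins - 1 - bins
        np.add.at(meth_sums, bins, m)
        np.add.at(total_sums, bins, t)

    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(total_sums > 0, meth_sums / total_sums, np.nan)
    return MetaProfile(context=context, flank_bp=flank_bp,
                       n_bins_body=n_bins_body, n_bins_flank=n_bins_flank,
                       levels=levels, meth_sums=meth_sums,
                       total_sums=total_sums)


def te_mean_levels(records: pd.DataFrame, tes: pd.DataFrame,
                   context: str = "CHH", min_reads: int = 5) -> pd.DataFrame:
    """Unweighted mean per-site methylation of each TE.

    For every TE, sites of *context* with depth ≥ *min_reads* inside the TE
    contribute their methylation fraction; the TE-level value is the plain
    mean of those fractions.  TEs with zero covered sites get ``NaN`` and
    ``n_sites = 0``.
    """
    sites = _site_arrays(records, context, min_reads)
    rows = []
    for f in tes.itertuples(index=False):
        te_id = getattr(f, "te_id", f"{f.chrom}:{f.start}-{f.end}")
        if f.chrom not in sites:
            rows.append({"te_id": te_id, "mean_site_level": np.nan,
                         "n_sites": 0})
            continue
        pos, meth, total = sites[f.chrom]
        lo = np.searchsorted(pos, int(f.start), side="left")
        hi = np.searchsorted(pos, int(f.end), side="left")
        if lo == hi:
            rows.append({"te_id": te_id, "mean_site_level": np.nan,
                         "n_sites": 0})
            continue
        fracs = meth[lo:hi] / total[lo:hi]
        rows.append({"te_id": te_id,
                     "mean_site_level": float(fracs.mean()),
                     "n_sites": int(hi - lo)})
    out = pd.DataFrame(rows, columns=["te_id", "mean_site_level", "n_sites"])
    out["context"] = context
    return out


def te_mean_level(records: pd.DataFrame, te, context: str = "CHH",
                  min_reads: int = 5) -> TELevel:
    """Mean per-site level of a single TE (row or interval-like object)."""
    te_df = pd.DataFrame(
        [{"chrom": te.chrom, "start": te.start, "end": te.end,
          "te_id": getattr(te, "te_id", f"{te.chrom}:{te.start}-{te.end}")}]
    )
    row = te_mean_levels(records, te_df, context=context,
                         min_reads=min_reads).iloc[0]
    return TELevel(te_id=row["te_id"], context=context,
                   mean_site_level=float(row["mean_site_level"]),
                   n_sites=int(row["n_sites"]))


def length_level_scatter(classified_tes: pd.DataFrame,
                         te_levels: pd.DataFrame) -> pd.DataFrame:
    """(length, level, class) tuples per TE, for length-vs-methylation plots.

    Joins classified TEs with their mean site levels on ``te_id``; TEs with
    undefined level (no covered sites) are excluded.
    """
    tes = classified_tes.copy()
    tes["length"] = tes["end"] - tes["start"]
    merged = tes.merge(te_levels[["te_id", "mean_site_level", "n_sites"]],
                       on="te_id", how="inner")
    merged = merged[merged["n_sites"] > 0]
    return merged[["te_id", "length", "mean_site_level", "dmr_class"]] \
        .rename(columns={"mean_site_level": "level"}) \
        .reset_index(drop=True)
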