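"""Readers and writers for the on-disk formats the pipeline touches.

All coordinates are normalized to 0-based half-open intervals internally;
conversion to/from 1-based conventions (cytosine reports, GFF3) happens only
at the I/O boundary.  Chromosome names are matched exactly — no ``Chr1``/``1``
aliasing — unless the caller supplies an explicit alias map.

The cytosine report dialect is the Bismark-style CX report: one line per
cytosine with columns ``chrom, pos (1-based), strand, count_methylated,
count_unmethylated, context, trinucleotide``.  Lines whose context is not one
of CG/CHG/CHH (e.g. CN/CHN at chromosome ends) are dropped; the number of
dropped lines is logged and recorded in ``DataFrame.attrs["n_skipped"]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: methylation contexts retained by the readers
CONTEXTS = ("CG", "CHG", "CHH")

#: column order of the in-memory cytosine table
CYTOSINE_COLUMNS = ("chrom", "pos", "strand", "meth", "unmeth", "context")


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's methylation evidence (``pos`` is 1-based)."""

    chrom: str
    pos: int
    strand: str
    context: str
    meth: int
    unmeth: int

    @property
    def depth(self) -> int:
        return self.meth + self.unmeth


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class StageSeries:
    """Ordered developmental stages with one cytosine table per stage.

    The default methylome staging is the five-point embryo series
    GL/H/T/BT/MG (globular, heart, torpedo, bending torpedo, mature green;
    4/5/7/9/12 days after pollination).  Stage order is preserved in every
    downstream output.
    """

    labels: tuple[str, ...]
    tables: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("stage labels must be unique")
        missing = [s for s in self.labels if s not in self.tables]
        if missing:
            raise ValueError(f"no cytosine table for stages: {missing}")

    def __iter__(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for label in self.labels:
            yield label, self.tables[label]


METHYLOME_STAGES = ("GL", "H", "T", "BT", "MG")


def _empty_cytosine_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "meth": pd.Series(dtype=np.int64),
            "unmeth": pd.Series(dtype=np.int64),
            "context": pd.Series(dtype=str),
        }
    )


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a CX-style cytosine report into a cytosine table.

    Returns a DataFrame with columns ``chrom, pos, strand, meth, unmeth,
    context`` in file order.  Records with zero total reads are retained
    (coverage filtering is an analysis decision, not a parsing one).
    Contexts outside CG/CHG/CHH are dropped; the count of dropped lines is in
    ``df.attrs["n_skipped"]``.

    Raises :class:`ValueError` naming the offending line for malformed lines
    or negative counts.
    """
    chroms: list[str] = []
    poss: list[int] = []
    strands: list[str] = []
    meths: list[int] = []
    unmeths: list[int] = []
    ctxs: list[str] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: malformed cytosine report line {lineno}: "
                    f"expected ≥6 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            if context not in CONTEXTS:
                n_skipped += 1
                continue
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed cytosine report line {lineno}: {exc}"
                ) from None
            if meth < 0 or unmeth < 0:
                raise ValueError(
                    f"{path}: negative read count on line {lineno}"
                )
            if pos < 1:
                raise ValueError(
                    f"{path}: position < 1 on line {lineno}"
                )
            chroms.append(chrom)
            poss.append(pos)
            strands.append(strand)
            meths.append(meth)
            unmeths.append(unmeth)
            ctxs.append(context)
    if n_skipped:
        logger.info("%s: skipped %d non-CG/CHG/CHH lines", path, n_skipped)
    if not chroms:
        df = _empty_cytosine_frame()
    else:
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": np.asarray(poss, dtype=np.int64),
                "strand": strands,
                "meth": np.asarray(meths, dtype=np.int64),
                "unmeth": np.asarray(unmeths, dtype=np.int64),
                "context": ctxs,
            }
        )
    df.attrs["n_skipped"] = n_skipped
    return df


def iter_cytosine_report(path) -> Iterator[CytosineRecord]:
    """Stream a cytosine report as :class:`CytosineRecord` objects."""
    df = read_cytosine_report(path)
    for row in df.itertuples(index=False):
        yield CytosineRecord(
            row.chrom, int(row.pos), row.strand, row.context,
            int(row.meth), int(row.unmeth),
        )


def write_cytosine_report(df: pd.DataFrame, path, trinucleotides=None) -> None:
    """Write a cytosine table as a 7-column CX report.

    The trinucleotide column is filled from *trinucleotides* (a sequence
    aligned with ``df``) or from the context label when not supplied.
    """
    out = df.copy()
    out["tri"] = (
        list(trinucleotides) if trinucleotides is not None else out["context"]
    )
    out[["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# interval formats
# ---------------------------------------------------------------------------

INTERVAL_COLUMNS = ("chrom", "start", "end")


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_intervals(path, fmt: str | None = None,
                   alias_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read BED or GFF3 intervals into a 0-based half-open interval table.

    *fmt* is ``"bed"`` or ``"gff3"``; if ``None`` it is inferred from the
    file extension.  BED input is taken as 0-based half-open, GFF3 as 1-based
    closed; both are normalized to 0-based half-open.  GFF3 ``attributes``
    key/value pairs become extra columns (e.g. ``superfamily``); BED columns
    4–6 become ``name``, ``score``, ``strand`` when present.

    *alias_map* optionally renames chromosomes (exact-string match otherwise).
    Raises :class:`ValueError` identifying the record if start ≥ end after
    normalization.
    """
    if fmt is None:
        lower = str(path).lower()
        if lower.endswith((".gff", ".gff3")):
            fmt = "gff3"
        elif lower.endswith((".bed", ".bedgraph")):
            fmt = "bed"
        else:
            raise ValueError(f"cannot infer interval format from {path!r}")
    fmt = fmt.lower()
    if fmt == "bed":
        df = _read_bed(path)
    elif fmt == "gff3":
        df = _read_gff3(path)
    else:
        raise ValueError(f"unsupported interval format {fmt!r}")
    if alias_map:
        df["chrom"] = df["chrom"].map(lambda c: alias_map.get(c, c))
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValueError(
            f"{path}: empty/inverted interval "
            f"{row['chrom']}:{row['start']}-{row['end']} (record {bad[0] + 1})"
        )
    if (df["start"] < 0).any():
        raise ValueError(f"{path}: negative start coordinate")
    return df


def _read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: BED line {lineno} has <3 fields")
            try:
                rec = {
                    "chrom": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                }
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer coordinate on BED line {lineno}"
                ) from None
            if len(fields) > 3:
                rec["name"] = fields[3]
            if len(fields) > 4:
                rec["score"] = fields[4]
            rec["strand"] = fields[5] if len(fields) > 5 else "."
            rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    df = pd.DataFrame(rows)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def _read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: GFF3 line {lineno} has {len(fields)} fields")
            try:
                start1 = int(fields[3])
                end1 = int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer coordinate on GFF3 line {lineno}"
                ) from None
            rec = {
                "chrom": fields[0],
                "source": fields[1],
                "type": fields[2],
                # 1-based closed -> 0-based half-open
                "start": start1 - 1,
                "end": end1,
                "strand": fields[6] if fields[6] in "+-" else ".",
            }
            rec.update(_parse_gff3_attributes(fields[8]))
            rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    df = pd.DataFrame(rows)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    """Write an interval table as BED3 (or BED4 with *name_col*)."""
    cols = [df["chrom"], df["start"], df["end"]]
    if name_col is not None:
        cols.append(df[name_col])
    pd.concat(cols, axis=1).to_csv(path, sep="\t", header=False, index=False)


def write_gff3(df: pd.DataFrame, path, feature_type: str = "transposable_element",
               source: str = "methylspread",
               attribute_cols: Iterable[str] = ()) -> None:
    """Write an interval table as GFF3 (converting to 1-based closed)."""
    attribute_cols = list(attribute_cols)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples(index=False):
            attrs = ";".join(
                f"{c}={getattr(row, c)}" for c in attribute_cols
            ) or "."
            strand = getattr(row, "strand", ".") or "."
            fh.write(
                f"{row.chrom}\t{source}\t{feature_type}\t{row.start + 1}\t"
                f"{row.end}\t.\t{strand}\t.\t{attrs}\n"
            )


def write_bedgraph(df: pd.DataFrame, path, value_col: str = "level",
                   header_comment: str | None = None) -> None:
    """Write chrom/start/end/value as bedGraph with an optional comment."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df[["chrom", "start", "end", value_col]].to_csv(
            fh, sep="\t", header=False, index=False, float_format="%.6g"
        )


def write_tsv(df: pd.DataFrame, path, params: Mapping[str, object] | None = None) -> None:
    """Write a TSV with a commented header naming the parameters used."""
    with open(path, "w") as fh:
        if params:
            rendered = " ".join(f"{k}={v}" for k, v in params.items())
            fh.write(f"# methylspread parameters: {rendered}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
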