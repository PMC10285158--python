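"""Cytosine-context frequencies of TE sequences and their analytic expectation.

The observed per-bp frequency of each methylation context in a sequence is
the context count divided by the sequence length.  The strand convention
mirrors the analytic expectation model: CG and CHG — both palindromic, so one
strand determines the other — are counted on the forward strand only, while
the asymmetric CHH context is counted on both strands (a reverse-strand CHH
appears on the forward strand as a D-D-G trinucleotide, D = A/G/T).

Under base probabilities p(A..T) the expected per-bp frequencies are

    CG  = p(C)·p(G)
    CHG = p(C)·p(H)·p(G)                    H = A/C/T,  p(H) = 1 − p(G)
    CHH = p(C)·p(H)² + p(D)²·p(G)           D = A/G/T,  p(D) = 1 − p(C)

where the second CHH term is the reverse strand (a reverse CHH reads D-D-G
on the forward strand).  When the composition is strand-symmetric
(p(C) = p(G)) this reduces to the familiar ``p(C)·p(H)·p(H) × 2``
double-strand form; under uniform composition the three expectations are
0.0625, 0.046875 and 0.28125 (0.063 / 0.047 / 0.28 at printed precision,
half-up).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

FLAG_HIGHER = "higher"
FLAG_LOWER = "lower"
FLAG_REFERENCE = "reference"
ALL_TES = "AllTEs"

_FLAG_TOL = 1e-12


@dataclass(frozen=True)
class ContextCounts:
    """Context occurrence counts of one sequence.

    ``n_chh`` includes both strands; frequencies are counts per bp of
    sequence length, so the CHH frequency can exceed 1 in principle.
    """

    n_cg: int
    n_chg: int
    n_chh: int
    length: int

    @property
    def frequencies(self) -> dict[str, float]:
        return {
            "CG": self.n_cg / self.length,
            "CHG": self.n_chg / self.length,
            "CHH": self.n_chh / self.length,
        }

    def __add__(self, other: "ContextCounts") -> "ContextCounts":
        return ContextCounts(
            self.n_cg + other.n_cg, self.n_chg + other.n_chg,
            self.n_chh + other.n_chh, self.length + other.length,
        )


def count_contexts(sequence: str) -> ContextCounts:
    """Count CG, CHG and CHH contexts in *sequence*.

    CG and CHG are forward-strand counts; CHH sums forward-strand C-H-H
    trinucleotides and reverse-strand ones (forward D-D-G, D = A/G/T).
    N bases contribute to no context; cytosines within the last one or two
    bases (no complete context) are not counted.
    """
    if not sequence:
        raise ValueError("empty sequence")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"
    is_h = (arr == b"A") | (arr == b"C") | (arr == b"T")
    is_d = (arr == b"A") | (arr == b"G") | (arr == b"T")
    n = len(arr)
    n_cg = int(np.count_nonzero(is_c[: n - 1] & is_g[1:])) if n >= 2 else 0
    if n >= 3:
        n_chg = int(np.count_nonzero(is_c[: n - 2] & is_h[1:-1] & is_g[2:]))
        chh_fwd = int(np.count_nonzero(is_c[: n - 2] & is_h[1:-1] & is_h[2:]))
        chh_rev = int(np.count_nonzero(is_d[: n - 2] & is_d[1:-1] & is_g[2:]))
    else:
        n_chg = chh_fwd = chh_rev = 0
    return ContextCounts(n_cg, n_chg, chh_fwd + chh_rev, n)


def expected_frequencies(base_prob: Mapping[str, float] | None = None
                         ) -> dict[str, float]:
    """Analytic per-bp expected context frequencies for a base composition.

    *base_prob* maps A/C/G/T to probabilities summing to 1 (uniform 0.25 by
    default).  CG and CHG are single-strand expectations; CHH sums both
    strands — forward ``p(C)·p(H)²`` plus reverse ``p(D)²·p(G)`` — which is
    the ×2 double-strand factor whenever p(C) = p(G).
    """
    if base_prob is None:
        base_prob = {b: 0.25 for b in "ACGT"}
    missing = set("ACGT") - set(base_prob)
    if missing:
        raise ValueError(f"base_prob lacks {sorted(missing)}")
    total = sum(base_prob[b] for b in "ACGT")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"base probabilities sum to {total}, not 1")
    if any(base_prob[b] < 0 for b in "ACGT"):
        raise ValueError("base probabilities must be non-negative")
    p_c = base_prob["C"]
    p_g = base_prob["G"]
    p_h = 1.0 - p_g
    p_d = 1.0 - p_c
    return {
        "CG": p_c * p_g,
        "CHG": p_c * p_h * p_g,
        "CHH": p_c * p_h * p_h + p_d * p_d * p_g,
    }


def printed_frequency(value: float, decimals: int) -> float:
    """Round a frequency the way the summary tables print it (half-up).

    Python's built-in ``round`` uses banker's rounding, which turns the
    uniform CG expectation 0.0625 into 0.062; tables conventionally print
    0.063.
    """
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum,
                                               rounding=ROUND_HALF_UP))


def _flag(value: float, reference: float) -> str:
    if value > reference + _FLAG_TOL:
        return FLAG_HIGHER
    if value < reference - _FLAG_TOL:
        return FLAG_LOWER
    return FLAG_REFERENCE


def _pool(counts: Sequence[ContextCounts], mode: str) -> dict[str, float]:
    if mode == "pooled":
        total = ContextCounts(0, 0, 0, 0)
        for c in counts:
            total = total + c
        return total.frequencies
    if mode == "mean":
        per_te = pd.DataFrame([c.frequencies for c in counts])
        return per_te.mean().to_dict()
    raise ValueError(f"unknown pooling mode {mode!r}")


def _fetch_sequence(fasta: Fasta, chrom: str, start: int, end: int) -> str | None:
    if chrom not in fasta:
        return None
    seq = str(fasta[chrom][start:end])
    return seq if seq else None


def frequency_table(classified_tes: pd.DataFrame, genome_fasta,
                    mode: str = "pooled") -> pd.DataFrame:
    """Observed context frequencies per (DMR class, superfamily) cell.

    Each cell pools its TEs length-weighted (Σ counts / Σ length; an
    unweighted per-TE mean is available with ``mode="mean"``).  An ``AllTEs``
    row per superfamily — computed over every input TE regardless of class —
    serves as the reference; each class cell carries ``higher``/``lower``/
    ``reference`` flags against it.  An ``Expectation`` row holds the uniform
    analytic model.  TEs without retrievable sequence are skipped with a
    warning.
    """
    from .classify import DMR_CLASSES

    fasta = Fasta(str(genome_fasta)) if not isinstance(genome_fasta, Fasta) \
        else genome_fasta
    tes = classified_tes.copy().reset_index(drop=True)
    counts: list[ContextCounts | None] = []
    n_skipped = 0
    for row in tes.itertuples(index=False):
        seq = _fetch_sequence(fasta, row.chrom, int(row.start), int(row.end))
        if seq is None:
            n_skipped += 1
            counts.append(None)
            continue
        counts.append(count_contexts(seq))
    if n_skipped:
        warnings.warn(f"{n_skipped} TE(s) without retrievable sequence skipped")
    tes["_counts"] = counts
    tes = tes[tes["_counts"].notna()]

    def cell(sub: pd.DataFrame) -> dict[str, float]:
        return _pool(list(sub["_counts"]), mode)

    rows = []
    exp = expected_frequencies()
    rows.append({"dmr_class": "Expectation", "superfamily": "all",
                 "n": 0, **{k: exp[k] for k in ("CG", "CHG", "CHH")},
                 "flag_CG": FLAG_REFERENCE, "flag_CHG": FLAG_REFERENCE,
                 "flag_CHH": FLAG_REFERENCE})
    superfamilies = sorted(tes["superfamily"].unique()) \
        if "superfamily" in tes.columns else ["all"]
    reference: dict[str, dict[str, float]] = {}
    for sf in superfamilies:
        sub = tes if sf == "all" else tes[tes["superfamily"] == sf]
        if len(sub) == 0:
            continue
        freqs = cell(sub)
        reference[sf] = freqs
        rows.append({"dmr_class": ALL_TES, "superfamily": sf, "n": len(sub),
                     **freqs, "flag_CG": FLAG_REFERENCE,
                     "flag_CHG": FLAG_REFERENCE, "flag_CHH": FLAG_REFERENCE})
    for cls in DMR_CLASSES:
        cls_tes = tes[tes["dmr_class"] == cls] if "dmr_class" in tes.columns \
            else tes.iloc[0:0]
        for sf in superfamilies:
            sub = cls_tes if sf == "all" else \
                cls_tes[cls_tes["superfamily"] == sf]
            if len(sub) == 0:
                continue
            freqs = cell(sub)
            ref = reference[sf]
            rows.append(
                {
                    "dmr_class": cls, "superfamily": sf, "n": len(sub),
                    **freqs,
                    "flag_CG": _flag(freqs["CG"], ref["CG"]),
                    "flag_CHG": _flag(freqs["CHG"], ref["CHG"]),
                    "flag_CHH": _flag(freqs["CHH"], ref["CHH"]),
                }
            )
    return pd.DataFrame(
        rows, columns=["dmr_class", "superfamily", "n", "CG", "CHG", "CHH",
                       "flag_CG", "flag_CHG", "flag_CHH"],
    )


def ltr_similarity_frequencies(ltrs: pd.DataFrame, genome_fasta,
                               similarity_bins: Sequence[float],
                               mode: str = "pooled") -> pd.DataFrame:
    """Pooled context frequencies of intact LTRs per similarity bin.

    *ltrs* carries chrom/start/end plus a ``similarity`` percentage in
    [0, 100] (LTR detection and dating are upstream inputs).
    *similarity_bins* are ascending edges; bin *i* is half-open
    ``[edge_i, edge_{i+1})`` with the last bin closed at the top.  Empty bins
    are omitted.
    """
    sims = ltrs["similarity"].to_numpy(dtype=float)
    if (sims < 0).any() or (sims > 100).any():
        raise ValueError("similarity values must lie in [0, 100]")
    edges = np.asarray(similarity_bins, dtype=float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("similarity_bins must be ≥2 ascending edges")
    fasta = Fasta(str(genome_fasta)) if not isinstance(genome_fasta, Fasta) \
        else genome_fasta
    idx = np.digitize(sims, edges[1:-1], right=False)
    in_range = (sims >= edges[0]) & (sims <= edges[-1])
    rows = []
    for b in range(len(edges) - 1):
        sub = ltrs[(idx == b) & in_range]
        if len(sub) == 0:
            continue
        counts = []
        for row in sub.itertuples(index=False):
            seq = _fetch_sequence(fasta, row.chrom, int(row.start),
                                  int(row.end))
            if seq is not None:
                counts.append(count_contexts(seq))
        if not counts:
            continue
        freqs = _pool(counts, mode)
        rows.append(
            {
                "bin_low": edges[b], "bin_high": edges[b + 1],
                "n": len(counts), **freqs,
            }
        )
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "n",
                                       "CG", "CHG", "CHH"])
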