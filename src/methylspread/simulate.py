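"""Ground-truth-labeled miniature embryo methylome simulator.

The generator emits everything the pipeline consumes — a random genome, a TE
annotation with pathway-class truth, per-class DMR lists, five stage-ordered
cytosine reports, and eight stages of 24-nt sRNA cluster intervals — with the
statistical structure the analysis assumes:

* CG methylation constant and high inside TEs across all five stages;
* CHG methylation inside TEs following a schedule that dips at the middle
  (torpedo) stage;
* CHH methylation concentrated in discrete blocks that extend spatially and
  rise in level stage by stage (the spreading signal);
* 24-nt sRNA clusters, a tunable fraction of which co-expand with CHH
  blocks over an eight-stage sRNA axis;
* cCMT2 TEs long and pericentromeric, cRdDM/eRdDM TEs short and arm-biased,
  each carrying one embedded same-class DMR so classification truth is
  recoverable.

Methylated CHH sites are placed on the genome's *actual* CHH positions
(contexts derived from the simulated sequence), so context frequencies and
methylation calls are mutually consistent.  Read depth is Poisson
(mean 40 by default) and methylated read counts are binomial at the site's
true level.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio

# fixed per-step offsets so each simulation step has its own stream but the
# whole run is reproducible from one seed
_GENOME_KEY = 11
_TE_KEY = 23
_METH_KEY = 37
_SRNA_KEY = 53

BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic embryo methylome.

    Defaults describe a miniature two-chromosome genome with uniform base
    composition, a central pericentromere occupying 40% of each chromosome,
    ~600 CHH blocks genome-wide that extend by 60 bp and gain 8 percentage
    points of methylation per stage, a mid-stage CHG dip, and half of the
    blocks co-expanding with 24-nt sRNA clusters.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pericentromere_fraction: float = 0.4
    stages: tuple[str, ...] = msio.METHYLOME_STAGES
    srna_stages: tuple[str, ...] = tuple(f"S{i}" for i in range(1, 9))

    # TE population (counts are per chromosome)
    te_counts: dict = field(default_factory=lambda: {
        "cCMT2": 40, "cRdDM": 60, "eRdDM": 50,
    })
    te_length_log_mean: dict = field(default_factory=lambda: {
        "cCMT2": np.log(3500.0), "cRdDM": np.log(600.0),
        "eRdDM": np.log(350.0),
    })
    te_length_log_sd: float = 0.35
    fraction_unassigned: float = 0.1   # TEs without any DMR (truth: unassigned)
    dmr_length: int = 150
    superfamily_probs: dict = field(default_factory=lambda: {
        "cCMT2": {"Gypsy": 0.55, "Copia": 0.2, "LINE": 0.1, "En-Spm": 0.1,
                  "MuDR": 0.05},
        "cRdDM": {"Helitron": 0.35, "MuDR": 0.25, "Copia": 0.15, "SINE": 0.1,
                  "Gypsy": 0.1, "En-Spm": 0.05},
        "eRdDM": {"Helitron": 0.3, "SINE": 0.25, "MuDR": 0.2, "Copia": 0.1,
                  "LINE": 0.1, "Gypsy": 0.05},
    })

    # CHH block dynamics
    n_blocks_per_chrom: int = 300
    block_initial_length: int = 200
    block_extension_bp: int = 60      # added per stage, split over both sides
    block_initial_level: float = 0.30
    block_level_increment: float = 0.08
    background_chh_level: float = 0.02

    # CG / CHG levels
    cg_te_level: float = 0.90
    cg_background_level: float = 0.20
    chg_te_schedule: tuple[float, ...] = (0.62, 0.60, 0.52, 0.58, 0.61)
    chg_background_level: float = 0.02

    depth_mean: float = 40.0

    # sRNA clusters
    srna_coexpansion_fraction: float = 0.5
    cluster_initial_length: int = 150
    cluster_extension_bp: int = 40    # per sRNA stage
    n_independent_clusters_per_chrom: int = 30
    independent_cluster_length: int = 200

    def validate(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.min() < 0 or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must be non-negative and sum to 1")
        if not 0 <= self.srna_coexpansion_fraction <= 1:
            raise ValueError("srna_coexpansion_fraction must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.block_extension_bp < 0 or self.cluster_extension_bp < 0:
            raise ValueError("extension rates must be ≥ 0")
        if len(self.chg_te_schedule) != len(self.stages):
            raise ValueError("chg_te_schedule must have one level per stage")

    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1}" for i in range(self.n_chromosomes)]


def _rng(config: SimulationConfig, key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, key])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random genome with the configured base composition (seed-stable)."""
    config.validate()
    rng = _rng(config, _GENOME_KEY)
    comp = np.asarray(config.base_composition, dtype=float)
    genome = {}
    for chrom in config.chrom_names():
        idx = rng.choice(4, size=config.chrom_length, p=comp)
        genome[chrom] = BASES[idx].tobytes().decode("ascii")
    return genome


def write_genome_fasta(genome: dict[str, str], path, line_width: int = 70
                       ) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# TEs and DMRs
# ---------------------------------------------------------------------------

def _slot_positions(region_start: int, region_end: int, n: int,
                    lengths: np.ndarray, rng: np.random.Generator
                    ) -> np.ndarray:
    """Non-overlapping start positions: one element per equal slot."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    slot_w = (region_end - region_start) / n
    starts = np.empty(n, dtype=np.int64)
    for i in range(n):
        lo = region_start + int(i * slot_w)
        hi = region_start + int((i + 1) * slot_w) - int(lengths[i])
        if hi <= lo:
            lengths[i] = max(50, int(slot_w * 0.8))
            hi = region_start + int((i + 1) * slot_w) - int(lengths[i])
        starts[i] = rng.integers(lo, max(hi, lo + 1))
    return starts


def _draw_superfamilies(probs: dict[str, float], n: int,
                        rng: np.random.Generator) -> np.ndarray:
    names = list(probs)
    p = np.asarray([probs[k] for k in names], dtype=float)
    p = p / p.sum()
    return np.array(names, dtype=object)[rng.choice(len(names), size=n, p=p)]


def simulate_te_annotation(config: SimulationConfig
                           ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """TE annotation with truth labels and per-class DMR lists.

    cCMT2 TEs are long (lognormal) and placed inside the pericentromere;
    cRdDM and eRdDM TEs are short and placed on the chromosome arms.  Each
    assigned TE embeds exactly one DMR of its own class, and class DMRs never
    overlap (TEs are placed in disjoint slots), so classification truth is
    recoverable.  A configured fraction of TEs receives no DMR (truth label
    ``unassigned``).

    Returns ``(te_table, dmrs_by_class)``; the TE table carries ``te_id``,
    ``superfamily``, ``true_class``.
    """
    config.validate()
    rng = _rng(config, _TE_KEY)
    L = config.chrom_length
    peri_half = config.pericentromere_fraction / 2.0
    peri_start = int(L * (0.5 - peri_half))
    peri_end = int(L * (0.5 + peri_half))

    te_rows = []
    dmr_rows: dict[str, list] = {c: [] for c in config.te_counts}
    te_counter = 0
    for chrom in config.chrom_names():
        # pericentromeric class
        n_peri = config.te_counts.get("cCMT2", 0)
        lengths = np.exp(rng.normal(config.te_length_log_mean["cCMT2"],
                                    config.te_length_log_sd,
                                    n_peri)).astype(np.int64)
        starts = _slot_positions(peri_start, peri_end, n_peri, lengths, rng)
        peri = [("cCMT2", s, l) for s, l in zip(starts, lengths)]

        # arm classes interleaved over both arms
        arm_classes = [c for c in ("cRdDM", "eRdDM")
                       for _ in range(config.te_counts.get(c, 0))]
        arm_classes = list(rng.permutation(np.array(arm_classes, dtype=object)))
        arm_lengths = np.array(
            [int(np.exp(rng.normal(config.te_length_log_mean[c],
                                   config.te_length_log_sd)))
             for c in arm_classes], dtype=np.int64,
        )
        n_arm = len(arm_classes)
        n_left = n_arm // 2
        left_starts = _slot_positions(1000, peri_start - 1000, n_left,
                                      arm_lengths[:n_left], rng)
        right_starts = _slot_positions(peri_end + 1000, L - 1000,
                                       n_arm - n_left,
                                       arm_lengths[n_left:], rng)
        arm = [(c, s, l) for c, s, l in
               zip(arm_classes, np.r_[left_starts, right_starts], arm_lengths)]

        for cls, start, length in peri + arm:
            te_id = f"TE{te_counter:05d}"
            te_counter += 1
            sf = _draw_superfamilies(config.superfamily_probs[cls], 1, rng)[0]
            assigned = rng.random() >= config.fraction_unassigned
            te_rows.append(
                {"chrom": chrom, "start": int(start),
                 "end": int(start + length), "te_id": te_id,
                 "superfamily": sf,
                 "true_class": cls if assigned else "unassigned"}
            )
            if assigned:
                dmr_len = min(config.dmr_length, int(length))
                off = rng.integers(0, max(int(length) - dmr_len, 0) + 1)
                dmr_rows[cls].append(
                    {"chrom": chrom, "start": int(start + off),
                     "end": int(start + off + dmr_len)}
                )
    tes = pd.DataFrame(te_rows).sort_values(["chrom", "start"]) \
        .reset_index(drop=True)
    dmrs = {
        cls: pd.DataFrame(rows, columns=["chrom", "start", "end"])
        for cls, rows in dmr_rows.items()
    }
    return tes, dmrs


# ---------------------------------------------------------------------------
# CHH block truth
# ---------------------------------------------------------------------------

def simulate_block_truth(config: SimulationConfig) -> pd.DataFrame:
    """Per-stage true extents of the CHH methylation blocks.

    Blocks are laid out in disjoint slots (so they never merge with each
    other even at full extension), start at ``block_initial_length`` and grow
    by ``block_extension_bp`` per stage, split evenly over both ends.  The
    per-stage methylation level is ``block_initial_level + s·increment``.

    Returns one row per (block, stage) with true start/end/level.
    """
    config.validate()
    rng = _rng(config, _METH_KEY)
    n_stage = len(config.stages)
    max_len = (config.block_initial_length
               + config.block_extension_bp * (n_stage - 1))
    rows = []
    block_id = 0
    for chrom in config.chrom_names():
        n = config.n_blocks_per_chrom
        slot_w = config.chrom_length / n
        if slot_w < max_len + 120:
            raise ValueError(
                "chromosome too short for the requested number of blocks at "
                "full extension"
            )
        for i in range(n):
            lo = int(i * slot_w) + 60 + max_len // 2
            hi = int((i + 1) * slot_w) - 60 - max_len // 2
            center = int(rng.integers(lo, max(hi, lo + 1)))
            for s, stage in enumerate(config.stages):
                half = (config.block_initial_length
                        + config.block_extension_bp * s) / 2.0
                level = min(
                    config.block_initial_level
                    + config.block_level_increment * s, 0.95,
                )
                rows.append(
                    {"block_id": f"B{block_id:05d}", "chrom": chrom,
                     "center": center, "stage": stage, "stage_index": s,
                     "start": int(round(center - half)),
                     "end": int(round(center + half)),
                     "level": level}
                )
            block_id += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _cytosine_sites(seq: str) -> pd.DataFrame:
    """All cytosines of both strands with their context, 1-based positions.

    Forward-strand cytosines are C bases; reverse-strand cytosines appear as
    G on the forward sequence.  Cytosines whose context runs off the
    chromosome end are omitted (their context is undefined).
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)
    is_c = arr == b"C"
    is_g = arr == b"G"
    is_h = (arr == b"A") | (arr == b"C") | (arr == b"T")
    is_d = (arr == b"A") | (arr == b"G") | (arr == b"T")

    ctx_fwd = np.full(n, b"", dtype="S3")
    ok = np.zeros(n, dtype=bool)
    # forward strand: C at i reads seq[i:i+3]
    cg = is_c.copy()
    cg[:-1] &= is_g[1:]
    cg[-1:] = False
    chg = is_c.copy()
    chg[:-2] &= ~is_g[1:-1] & is_h[1:-1] & is_g[2:]
    chg[-2:] = False
    chh = is_c.copy()
    chh[:-2] &= is_h[1:-1] & is_h[2:]
    chh[-2:] = False
    chh &= ~cg  # CG takes precedence: C followed by G is CG regardless
    ctx_fwd[cg] = b"CG"
    ctx_fwd[chg] = b"CHG"
    ctx_fwd[chh] = b"CHH"
    ok = cg | chg | chh

    # reverse strand: C at i (forward G) reads complement of seq[i-2:i+1]
    rcg = is_g.copy()
    rcg[1:] &= is_c[:-1]
    rcg[:1] = False
    rchg = is_g.copy()
    rchg[2:] &= ~is_c[1:-1] & is_d[1:-1] & is_c[:-2]
    rchg[:2] = False
    rchh = is_g.copy()
    rchh[2:] &= is_d[1:-1] & is_d[:-2]
    rchh[:2] = False
    rchh &= ~rcg
    ctx_rev = np.full(n, b"", dtype="S3")
    ctx_rev[rcg] = b"CG"
    ctx_rev[rchg] = b"CHG"
    ctx_rev[rchh] = b"CHH"
    ok_rev = rcg | rchg | rchh

    pos_f = np.flatnonzero(ok)
    pos_r = np.flatnonzero(ok_rev)
    df = pd.DataFrame(
        {
            "pos": np.r_[pos_f + 1, pos_r + 1].astype(np.int64),
            "strand": np.r_[np.full(len(pos_f), "+", dtype=object),
                            np.full(len(pos_r), "-", dtype=object)],
            "context": np.r_[ctx_fwd[pos_f], ctx_rev[pos_r]].astype(str),
        }
    ).sort_values("pos", kind="mergesort").reset_index(drop=True)
    return df


def _interval_membership(pos0: np.ndarray, starts: np.ndarray,
                         ends: np.ndarray) -> np.ndarray:
    """Boolean membership of positions in disjoint sorted intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos0), dtype=bool)
    idx = np.searchsorted(starts, pos0, side="right") - 1
    return (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])


def simulate_methylome(config: SimulationConfig, genome: dict[str, str],
                       tes: pd.DataFrame, block_truth: pd.DataFrame
                       ) -> dict[str, pd.DataFrame]:
    """Five per-stage cytosine tables with the configured dynamics.

    Per stage and site: depth ~ Poisson(depth_mean) and methylated reads ~
    Binomial(depth, level), where the level is set by context and location —
    CG high inside TEs, CHG following the dip schedule inside TEs, CHH at the
    block's stage level inside blocks and at background elsewhere.
    """
    config.validate()
    rng = _rng(config, _METH_KEY + 1)
    sites_by_chrom = {c: _cytosine_sites(genome[c]) for c in genome}
    reports: dict[str, pd.DataFrame] = {}
    for s, stage in enumerate(config.stages):
        parts = []
        for chrom in config.chrom_names():
            sites = sites_by_chrom[chrom]
            pos0 = sites["pos"].to_numpy(dtype=np.int64) - 1
            level = np.empty(len(sites), dtype=float)

            te_sub = tes[tes["chrom"] == chrom].sort_values("start")
            in_te = _interval_membership(
                pos0, te_sub["start"].to_numpy(np.int64),
                te_sub["end"].to_numpy(np.int64),
            )
            blk = block_truth[(block_truth["chrom"] == chrom)
                              & (block_truth["stage"] == stage)] \
                .sort_values("start")
            in_block = _interval_membership(
                pos0, blk["start"].to_numpy(np.int64),
                blk["end"].to_numpy(np.int64),
            )
            is_cg = (sites["context"] == "CG").to_numpy()
            is_chg = (sites["context"] == "CHG").to_numpy()
            is_chh = (sites["context"] == "CHH").to_numpy()

            level[is_cg] = np.where(in_te[is_cg], config.cg_te_level,
                                    config.cg_background_level)
            level[is_chg] = np.where(in_te[is_chg],
                                     config.chg_te_schedule[s],
                                     config.chg_background_level)
            block_level = (config.block_initial_level
                           + config.block_level_increment * s)
            level[is_chh] = np.where(in_block[is_chh],
                                     min(block_level, 0.95),
                                     config.background_chh_level)

            depth = rng.poisson(config.depth_mean, size=len(sites))
            meth = rng.binomial(depth, level)
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": sites["pos"].to_numpy(np.int64),
                        "strand": sites["strand"].to_numpy(),
                        "meth": meth.astype(np.int64),
                        "unmeth": (depth - meth).astype(np.int64),
                        "context": sites["context"].to_numpy(),
                    }
                )
            )
        reports[stage] = pd.concat(parts, ignore_index=True)
    return reports


# ---------------------------------------------------------------------------
# sRNA clusters
# ---------------------------------------------------------------------------

def simulate_srna_clusters(config: SimulationConfig,
                           block_truth: pd.DataFrame
                           ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Eight per-stage 24-nt sRNA cluster tables plus co-expansion truth.

    A fraction ``srna_coexpansion_fraction`` of the CHH blocks receives a
    co-located cluster centered on the block that extends by
    ``cluster_extension_bp`` per sRNA stage; the remaining clusters are
    placed independently (uniformly at random) with a fixed length.

    Returns ``(clusters_by_stage, coexpansion_truth)`` where the truth table
    has one row per block with a boolean ``has_cluster``.
    """
    config.validate()
    rng = _rng(config, _SRNA_KEY)
    blocks = block_truth[block_truth["stage_index"] == 0][
        ["block_id", "chrom", "center"]].reset_index(drop=True)
    n_blocks = len(blocks)
    n_co = int(round(config.srna_coexpansion_fraction * n_blocks))
    chosen = np.zeros(n_blocks, dtype=bool)
    chosen[rng.permutation(n_blocks)[:n_co]] = True
    truth = blocks.copy()
    truth["has_cluster"] = chosen

    clusters_by_stage: dict[str, pd.DataFrame] = {}
    for s, stage in enumerate(config.srna_stages):
        rows = []
        half = (config.cluster_initial_length
                + config.cluster_extension_bp * s) / 2.0
        for row in blocks[chosen].itertuples(index=False):
            rows.append(
                {"chrom": row.chrom,
                 "start": max(0, int(round(row.center - half))),
                 "end": int(round(row.center + half)),
                 "size_class": "24nt"}
            )
        for chrom in config.chrom_names():
            starts = rng.integers(
                0, config.chrom_length - config.independent_cluster_length,
                size=config.n_independent_clusters_per_chrom,
            )
            for st in starts:
                rows.append(
                    {"chrom": chrom, "start": int(st),
                     "end": int(st + config.independent_cluster_length),
                     "size_class": "24nt"}
                )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "size_class"])
        clusters_by_stage[stage] = df.sort_values(["chrom", "start"]) \
            .reset_index(drop=True)
    return clusters_by_stage, truth


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """In-memory bundle of one simulation run with its ground truth."""

    config: SimulationConfig
    genome: dict[str, str]
    tes: pd.DataFrame
    dmrs: dict[str, pd.DataFrame]
    block_truth: pd.DataFrame
    methylomes: dict[str, pd.DataFrame]
    srna_clusters: dict[str, pd.DataFrame]
    srna_truth: pd.DataFrame

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_dataset(config: SimulationConfig | None = None,
                     ) -> SimulatedDataset:
    """Run the full generator and return the in-memory dataset."""
    config = config or SimulationConfig()
    genome = simulate_genome(config)
    tes, dmrs = simulate_te_annotation(config)
    block_truth = simulate_block_truth(config)
    methylomes = simulate_methylome(config, genome, tes, block_truth)
    srna_clusters, srna_truth = simulate_srna_clusters(config, block_truth)
    return SimulatedDataset(config, genome, tes, dmrs, block_truth,
                            methylomes, srna_clusters, srna_truth)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write a dataset to disk in the pipeline's input formats.

    Emits ``genome.fa``, ``tes.gff3``, ``dmr_<class>.bed``, per-stage
    ``methylome_<stage>.cx.tsv`` reports and ``srna_<stage>.bed`` cluster
    files, plus truth TSVs.  Returns a name→path manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    fasta = outdir / "genome.fa"
    write_genome_fasta(ds.genome, fasta)
    manifest["genome"] = str(fasta)

    gff = outdir / "tes.gff3"
    msio.write_gff3(ds.tes, gff, attribute_cols=("te_id", "superfamily"))
    manifest["tes"] = str(gff)

    for cls, dmr in ds.dmrs.items():
        path = outdir / f"dmr_{cls}.bed"
        msio.write_bed(dmr, path)
        manifest[f"dmr_{cls}"] = str(path)

    for stage, report in ds.methylomes.items():
        path = outdir / f"methylome_{stage}.cx.tsv"
        msio.write_cytosine_report(report, path)
        manifest[f"methylome_{stage}"] = str(path)

    for stage, clusters in ds.srna_clusters.items():
        path = outdir / f"srna_{stage}.bed"
        msio.write_bed(clusters, path, name_col="size_class")
        manifest[f"srna_{stage}"] = str(path)

    te_truth = outdir / "te_truth.tsv"
    ds.tes.to_csv(te_truth, sep="\t", index=False)
    manifest["te_truth"] = str(te_truth)
    block_truth = outdir / "block_truth.tsv"
    ds.block_truth.to_csv(block_truth, sep="\t", index=False)
    manifest["block_truth"] = str(block_truth)
    srna_truth = outdir / "srna_truth.tsv"
    ds.srna_truth.to_csv(srna_truth, sep="\t", index=False)
    manifest["srna_truth"] = str(srna_truth)

    config_json = outdir / "config.json"
    cfg = asdict(ds.config)
    cfg["base_composition"] = list(cfg["base_composition"])
    import json

    config_json.write_text(json.dumps(cfg, indent=2, default=str) + "\n")
    manifest["config"] = str(config_json)
    return manifest
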