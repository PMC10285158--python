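"""End-to-end pipeline: chain every analysis stage on one input directory.

``run_all`` wires the modules together in the paper-mode configuration
(50/10 bp windows, cutoffs 5/10/15%, <40 bp block gap, ≤75 bp cluster gap,
3-of-5 block consensus, 5-of-8 sRNA consensus) and writes TSV/BED outputs
plus a provenance manifest (parameters, input checksums, package version).
Re-running with an identical config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import blocks as blocks_mod
from . import classify as classify_mod
from . import context_freq
from . import io as msio
from . import metaplot as metaplot_mod
from . import srna as srna_mod
from . import windows as windows_mod
from .simulate import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

#: the analysis defaults used throughout ("paper mode")
DEFAULT_PARAMS = {
    "window_size": 50,
    "min_cytosines": 3,
    "min_reads": 5,
    "global_window_size": 5000,
    "global_min_cytosines": 10,   # strictly more than this
    "block_window_size": 10,
    "block_min_sites": 1,
    "block_cutoffs": (0.05, 0.10, 0.15),
    "block_max_gap": 40,          # strict <
    "consensus_cutoff": 0.15,
    "consensus_min_stages": 3,
    "srna_max_gap": 75,           # inclusive ≤
    "srna_min_stages": 5,
    "positional_bins": 20,
}


@dataclass
class RunConfig:
    """Configuration of one ``run_all`` execution.

    With ``input_dir=None`` the synthetic generator provides the inputs
    (written under ``<outdir>/simulated``); otherwise the directory must hold
    the file layout :func:`methylspread.simulate.write_dataset` produces.
    """

    outdir: str
    seed: int = 0
    input_dir: str | None = None
    simulation: SimulationConfig | None = None
    params: dict = field(default_factory=dict)
    stages: tuple[str, ...] = msio.METHYLOME_STAGES
    srna_stages: tuple[str, ...] = tuple(f"S{i}" for i in range(1, 9))

    def resolved_params(self) -> dict:
        out = dict(DEFAULT_PARAMS)
        out.update(self.params)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_paths(indir: Path, config: RunConfig) -> dict[str, Path]:
    paths = {"genome": indir / "genome.fa", "tes": indir / "tes.gff3"}
    for cls in classify_mod.DMR_CLASSES:
        paths[f"dmr_{cls}"] = indir / f"dmr_{cls}.bed"
    for stage in config.stages:
        paths[f"methylome_{stage}"] = indir / f"methylome_{stage}.cx.tsv"
    for stage in config.srna_stages:
        paths[f"srna_{stage}"] = indir / f"srna_{stage}.bed"
    missing = [f"{k} ({v})" for k, v in paths.items() if not v.exists()]
    if missing:
        raise FileNotFoundError(
            "missing pipeline inputs: " + ", ".join(missing)
        )
    return paths


def run_all(config: RunConfig) -> dict:
    """Run the full analysis and return the provenance manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.resolved_params()
    steps: list[str] = []

    if config.input_dir is None:
        sim_config = config.simulation or SimulationConfig(seed=config.seed)
        logger.info("simulate: generating synthetic dataset (seed=%d)",
                    sim_config.seed)
        ds = simulate_dataset(sim_config)
        indir = outdir / "simulated"
        write_dataset(ds, indir)
        steps.append("simulate")
    else:
        indir = Path(config.input_dir)
    inputs = _input_paths(indir, config)

    tes = msio.read_intervals(inputs["tes"], fmt="gff3")
    methylomes = {
        stage: msio.read_cytosine_report(inputs[f"methylome_{stage}"])
        for stage in config.stages
    }

    # -- windows ------------------------------------------------------------
    logger.info("windows: %d bp shared windows", params["window_size"])
    win_dir = outdir / "windows"
    win_dir.mkdir(exist_ok=True)
    window_rows = []
    for context in ("CG", "CHG", "CHH"):
        per_stage = {}
        for stage in config.stages:
            win = windows_mod.windowed_levels(
                methylomes[stage], params["window_size"],
                min_cytosines=params["min_cytosines"],
                min_reads_per_cytosine=params["min_reads"], context=context,
            )
            per_stage[stage] = win
            msio.write_bedgraph(
                win, win_dir / f"windows_{context}_{stage}.bedgraph",
                header_comment=(
                    f"context={context} stage={stage} "
                    f"size={params['window_size']} "
                    f"min_c={params['min_cytosines']} "
                    f"min_depth={params['min_reads']}"
                ),
            )
        shared = windows_mod.shared_windows(per_stage)
        for stage in config.stages:
            window_rows.append(
                {"context": context, "stage": stage,
                 "mean_level": float(shared[f"level_{stage}"].mean())
                 if len(shared) else float("nan"),
                 "n_windows": len(shared)}
            )
    msio.write_tsv(pd.DataFrame(window_rows),
                   outdir / "window_levels_by_stage.tsv", params=params)
    steps.append("windows")

    # -- blocks -------------------------------------------------------------
    logger.info("blocks: spreading statistic at cutoffs %s",
                params["block_cutoffs"])
    block_stats = []
    consensus_windows = []
    for cutoff in params["block_cutoffs"]:
        per_stage_blocks = {}
        for stage in config.stages:
            qwin = blocks_mod.qualifying_windows(
                methylomes[stage], cutoff,
                window_size=params["block_window_size"],
                min_sites=params["block_min_sites"],
                min_reads=params["min_reads"],
            )
            per_stage_blocks[stage] = blocks_mod.merge_blocks(
                qwin, max_gap=params["block_max_gap"],
            )
            if cutoff == params["consensus_cutoff"]:
                consensus_windows.append(qwin)
        stats = blocks_mod.block_length_stats(per_stage_blocks)
        stats.insert(0, "cutoff", cutoff)
        block_stats.append(stats)
    msio.write_tsv(pd.concat(block_stats, ignore_index=True),
                   outdir / "block_length_by_stage.tsv", params=params)
    consensus = blocks_mod.consensus_chh_blocks(
        consensus_windows, min_stages=params["consensus_min_stages"],
        max_gap=params["block_max_gap"],
    )
    msio.write_bed(consensus, outdir / "consensus_chh_blocks.bed")
    steps.append("blocks")

    # -- sRNA ---------------------------------------------------------------
    logger.info("srna: consensus clusters and block overlap")
    merged_by_stage = []
    for stage in config.srna_stages:
        clusters = msio.read_intervals(inputs[f"srna_{stage}"], fmt="bed")
        merged_by_stage.append(
            srna_mod.merge_srna_clusters(clusters,
                                         max_gap=params["srna_max_gap"])
        )
    consensus_clu = srna_mod.consensus_clusters(
        merged_by_stage, min_stages=params["srna_min_stages"],
        max_gap=params["srna_max_gap"],
    )
    msio.write_bed(consensus_clu, outdir / "consensus_srna_clusters.bed")
    groups = srna_mod.classify_block_overlap(consensus, consensus_clu)
    msio.write_tsv(srna_mod.overlap_group_stats(groups),
                   outdir / "block_srna_overlap_stats.tsv", params=params)
    steps.append("srna")

    # -- classify -----------------------------------------------------------
    logger.info("classify: TE pathway classes")
    dmrs = {
        cls: msio.read_intervals(inputs[f"dmr_{cls}"], fmt="bed")
        for cls in classify_mod.DMR_CLASSES
    }
    classified = classify_mod.assign_dmr_class(tes, dmrs)
    classified.to_csv(outdir / "classified_tes.tsv", sep="\t", index=False)
    for cls in classify_mod.DMR_CLASSES:
        msio.write_bed(classified[classified["dmr_class"] == cls],
                       outdir / f"tes_{cls}.bed", name_col="te_id")
    msio.write_tsv(classify_mod.class_length_summary(classified),
                   outdir / "te_class_lengths.tsv", params=params)
    msio.write_tsv(classify_mod.superfamily_composition(classified),
                   outdir / "te_superfamily_composition.tsv", params=params)
    chrom_sizes = _fasta_sizes(inputs["genome"])
    pos_rows = []
    first_chrom = sorted(chrom_sizes)[0]
    for cls in classify_mod.DMR_CLASSES:
        sub = classified[(classified["dmr_class"] == cls)
                         & (classified["chrom"] == first_chrom)]
        if len(sub) == 0:
            continue
        frac = classify_mod.positional_distribution(
            sub, chrom_sizes[first_chrom], params["positional_bins"],
        )
        for i, f in enumerate(frac):
            pos_rows.append({"dmr_class": cls, "chrom": first_chrom,
                             "bin": i, "fraction": f})
    msio.write_tsv(pd.DataFrame(pos_rows),
                   outdir / "te_positional_distribution.tsv", params=params)
    steps.append("classify")

    # -- context frequencies -------------------------------------------------
    logger.info("freq: cytosine-context frequency table")
    table = context_freq.frequency_table(classified, inputs["genome"])
    msio.write_tsv(table, outdir / "context_frequency_table.tsv",
                   params=params)
    steps.append("freq")

    # -- metaplot -----------------------------------------------------------
    logger.info("metaplot: TE metaprofiles and per-TE levels")
    profiles = []
    for context in ("CG", "CHG", "CHH"):
        for stage in config.stages:
            prof = metaplot_mod.feature_metaprofile(
                methylomes[stage], tes, context=context,
                min_reads=params["min_reads"],
            )
            frame = prof.to_frame()
            frame.insert(0, "stage", stage)
            frame.insert(0, "context", context)
            profiles.append(frame)
    msio.write_tsv(pd.concat(profiles, ignore_index=True),
                   outdir / "te_metaprofiles.tsv", params=params)
    last_stage = config.stages[-1]
    levels = metaplot_mod.te_mean_levels(methylomes[last_stage], tes,
                                         context="CHH",
                                         min_reads=params["min_reads"])
    scatter = metaplot_mod.length_level_scatter(classified, levels)
    msio.write_tsv(scatter, outdir / "te_length_vs_level.tsv", params=params)
    steps.append("metaplot")

    manifest = {
        "package": "methylspread",
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in params.items()},
        "stages": list(config.stages),
        "srna_stages": list(config.srna_stages),
        "steps": steps,
        # paths relative to outdir so reruns into different directories are
        # byte-comparable
        "inputs": {k: {"path": _relative_to(v, outdir), "sha256": _sha256(v)}
                   for k, v in sorted(inputs.items())},
        "simulation": (
            None if config.input_dir is not None else
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in dataclasses.asdict(
                 config.simulation or SimulationConfig(seed=config.seed)
             ).items()}
        ),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest


def _relative_to(path: Path, outdir: Path) -> str:
    try:
        return str(path.resolve().relative_to(outdir.resolve()))
    except ValueError:
        return str(path)


def _fasta_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    name = None
    n = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sizes[name] = n
                name = line[1:].split()[0]
                n = 0
            else:
                n += len(line)
    if name is not None:
        sizes[name] = n
    return sizes
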