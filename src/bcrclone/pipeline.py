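"""End-to-end orchestration: simulate -> read -> annotate -> clonotype ->
share -> lineage, with a manifest and run log.

Every output is a plain-text table (TSV), FASTA or newick file; the manifest
records each file with a content hash so that two runs with the same seed
and config are byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clonotyping, io as rio, lineage, mutations, sharing
from .errors import BcrcloneError, ConfigurationError
from .io import ISOTYPES, POPULATIONS
from .simulate import SimulationConfig, simulate_repertoire

logger = logging.getLogger(__name__)

_FAMILY = re.compile(r"^IGH([VDJ])(\d+)\D")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``airr_path`` + germline paths point at existing inputs, or
    ``simulation`` describes a repertoire to generate first.
    """

    output_dir: str = "bcrclone_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    airr_path: str | None = None
    germline_fasta: str | None = None
    germline_regions: str | None = None
    clone_threshold: float = clonotyping.DEFAULT_CLONE_THRESHOLD
    clonotype_scope: str = "per_isotype"
    mutation_bins: tuple = mutations.DEFAULT_BINS
    transition_mode: str = "edge"
    top_n_trees: int = 10
    max_tree_nodes: int = 150
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 <= self.clone_threshold <= 1.0:
            raise ConfigurationError("clone_threshold must be in [0, 1]")
        if self.simulation is None and self.airr_path is None:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        bins = d.pop("mutation_bins", None)
        cfg = cls(**d)
        if sim is not None:
            cfg.simulation = SimulationConfig.from_dict(sim)
        if bins is not None:
            cfg.mutation_bins = tuple((lo, hi) for lo, hi in bins)
        return cfg


def summarize_family_usage(records: pd.DataFrame) -> pd.DataFrame:
    """Per population x isotype proportions of V families (sum to 1 per sample)."""
    fam = records["v_call"].map(rio.family_of)
    work = records.assign(v_family=fam)
    counts = (
        work.groupby(["population", "isotype", "v_family"], sort=True)
        .size().rename("n").reset_index()
    )
    totals = counts.groupby(["population", "isotype"])["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    return counts


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the manifest dict.

    Emits mutation tables, the per-isotype sharing summaries, the overlap
    matrix, k-way sharing counts, the single-vs-shared comparison, V-family
    usage, clonal-group assignments and top-clone lineage trees with
    ancestor/progeny transition counts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("bcrclone")
    root.addHandler(handler)
    root.setLevel(config.log_level)

    manifest: dict = {"outputs": {}, "stages": [], "config": _config_dict(config)}
    try:
        _run_stages(config, out, manifest)
        manifest["status"] = "ok"
    except BcrcloneError as exc:
        logger.error("pipeline failed: %s", exc)
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        raise
    finally:
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name not in ("run.log", "manifest.json"):
                rel = str(path.relative_to(out))
                manifest["outputs"][rel] = {
                    "sha256": _sha256(path), "bytes": path.stat().st_size,
                }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        root.removeHandler(handler)
        handler.close()
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["mutation_bins"] = [list(b) for b in config.mutation_bins]
    return d


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> None:
    # -- inputs ------------------------------------------------------------
    if config.airr_path is not None:
        if not Path(config.airr_path).exists():
            raise ConfigurationError(f"input not found: {config.airr_path}")
        records = rio.read_airr(config.airr_path)
        germlines = rio.read_germlines(config.germline_fasta, config.germline_regions)
        truth_records = None
    else:
        logger.info("simulating repertoire (seed=%d)", config.simulation.seed)
        records, truth_records, truth_clones, germlines = simulate_repertoire(
            config.simulation)
        rio.write_airr(records, out / "airr.tsv")
        _write_tsv(truth_records, out / "truth_records.tsv")
        _write_tsv(truth_clones, out / "truth_clones.tsv")
        rio.write_germlines(germlines, out / "germlines.fasta",
                            out / "germline_regions.tsv")
        records = rio.read_airr(out / "airr.tsv")
    manifest["stages"].append({"stage": "input", "n_records": len(records)})

    # -- deduplicate + annotate -------------------------------------------
    unique = clonotyping.deduplicate(records)
    unique = mutations.fill_germlines(unique, germlines)
    rio.write_airr(unique, out / "unique.tsv")

    profiles = mutations.profiles_frame(unique, germlines)
    _write_tsv(profiles, out / "mutation_profiles.tsv")
    summary = mutations.aggregate_profiles(profiles, bins=config.mutation_bins)
    _write_tsv(summary, out / "mutation_summary.tsv")
    _write_tsv(summarize_family_usage(unique), out / "family_usage.tsv")
    manifest["stages"].append({"stage": "mutations", "n_unique": len(unique)})

    # -- clonotypes and sharing -------------------------------------------
    clonotypes, membership = clonotyping.define_cdr3_clonotypes(
        unique, scope=config.clonotype_scope)
    _write_tsv(clonotypes, out / "clonotypes.tsv")
    _write_tsv(membership, out / "clonotype_membership.tsv")

    for isotype in ISOTYPES:
        table = sharing.build_sharing_table(clonotypes, isotype)
        if table.total_clones:
            _write_tsv(sharing.sharing_table_frame(table),
                       out / f"sharing_table_{isotype}.tsv")

    mat = sharing.overlap_matrix(sharing.junction_sets(unique))
    mat.to_csv(out / "overlap_matrix.tsv", sep="\t", lineterminator="\n")

    kway = pd.concat(
        [sharing.kway_sharing(clonotypes[clonotypes["isotype"] == iso], k)
         .assign(isotype=iso)
         for iso in ISOTYPES for k in (2, 3, 4)
         if (clonotypes["isotype"] == iso).any()],
        ignore_index=True,
    ) if config.clonotype_scope == "per_isotype" else pd.concat(
        [sharing.kway_sharing(clonotypes, k) for k in (2, 3, 4)], ignore_index=True)
    _write_tsv(kway, out / "kway_sharing.tsv")

    _write_tsv(sharing.shared_vs_single_shm(profiles, membership, clonotypes),
               out / "shared_vs_single.tsv")
    manifest["stages"].append({"stage": "sharing", "n_clonotypes": len(clonotypes)})

    # -- clonal groups and lineage trees ----------------------------------
    grouped = clonotyping.group_clones(unique, threshold=config.clone_threshold)
    rio.write_airr(grouped, out / "clone_assignments.tsv")
    _write_tsv(clonotyping.distance_to_nearest(unique),
               out / "distance_to_nearest.tsv")

    clone_summary = (
        grouped.groupby("clone_id", sort=True)
        .agg(sequence_count=("sequence_id", "size"),
             v_call=("v_call", "first"), j_call=("j_call", "first"))
        .reset_index()
    )
    _write_tsv(clone_summary, out / "clone_summary.tsv")
    top = lineage.select_top_clones(clone_summary, n=config.top_n_trees)

    transition_frames = []
    for row in top.itertuples(index=False):
        members = grouped[grouped["clone_id"] == row.clone_id]
        lengths = members["sequence_alignment"].str.len()
        if lengths.nunique() > 1:
            # clones merged across rearrangements of unequal alignment length
            # cannot share one germline; keep the dominant length
            keep = lengths.eq(lengths.mode().iloc[0])
            logger.warning("clone %s: dropping %d members with off-length alignments",
                           row.clone_id, int((~keep).sum()))
            members = members[keep]
        nodes = lineage.collapse_identical(members)
        if len(nodes) > config.max_tree_nodes:
            logger.warning("clone %s: truncating %d nodes to most abundant %d",
                           row.clone_id, len(nodes), config.max_tree_nodes)
            nodes = nodes[: config.max_tree_nodes]
        germ = members.iloc[0]["germline_alignment"]
        tree = lineage.build_parsimony_tree(nodes, germ)
        node_table = lineage.annotate_overlap_nodes(tree)
        (out / "trees" / f"{row.clone_id}.nwk").write_text(tree.to_newick() + "\n")
        _write_tsv(node_table, out / "trees" / f"{row.clone_id}_nodes.tsv")
        trans = lineage.ancestor_progeny_transitions(tree, mode=config.transition_mode)
        trans_path = lineage.ancestor_progeny_transitions(tree, mode="path")
        transition_frames.append(trans.assign(clone_id=row.clone_id, mode="edge"))
        transition_frames.append(trans_path.assign(clone_id=row.clone_id, mode="path"))
    if transition_frames:
        _write_tsv(pd.concat(transition_frames, ignore_index=True),
                   out / "transitions.tsv")
    manifest["stages"].append({"stage": "lineage", "n_trees": len(top)})
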