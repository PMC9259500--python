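"""End-to-end orchestration: simulate -> qc -> cluster -> novelty -> profile -> structure.

Runs the stages in analysis order on a seeded synthetic universe (or on
user-provided tables via the CLI stage commands), writes each stage's TSV/
JSON outputs plus a manifest (parameters, seed, input hashes), and
aggregates a report with the headline counts and "count (percent%)"
summary strings.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bgc_families, community, genome_qc, novelty, profiling
from .io import file_sha256, write_json, write_matrix, write_tsv
from .simulate import SimulationConfig, simulate_bgc_universe, simulate_genome_collection, simulate_profiles, simulate_reference_db

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "render_summary"]


@dataclass
class PipelineConfig:
    """Thresholds (paper-default), stage toggles and the root seed."""

    seed: int = 0
    t_gcf: float = bgc_families.GCF_THRESHOLD
    t_gcc: float = bgc_families.GCC_THRESHOLD
    novelty_gcf: float = novelty.GCF_NOVELTY_THRESHOLD
    novelty_gcc: float = novelty.GCC_NOVELTY_THRESHOLD
    scaffold_min_bp: int = bgc_families.SCAFFOLD_MIN_BP
    ani_threshold: float = genome_qc.SPECIES_ANI_THRESHOLD
    completeness_floor: float = 70.0
    bgc_rich_floor: int = community.BGC_RICH_FLOOR
    n_permutations: int = 999
    run_profiling: bool = True
    run_structure: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(simulation=sim, **raw)
        if not 0 < cfg.t_gcf < cfg.t_gcc <= 1:
            raise ValueError("need 0 < t_gcf < t_gcc <= 1")
        return cfg


def _manifest(out_dir: Path, stage: str, params: dict, outputs: list, seed: int):
    entry = {
        "stage": stage,
        "seed": seed,
        "parameters": params,
        "outputs": {str(Path(p).name): file_sha256(p) for p in outputs},
    }
    write_json(entry, out_dir / f"manifest_{stage}.json")
    return entry


def run_pipeline(config: PipelineConfig | dict, out_dir) -> dict:
    """Execute every enabled stage on the seeded synthetic universe.

    Returns the aggregated report (also written to ``report.json``); all
    machine outputs land under ``out_dir`` with per-stage manifests.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_dir = out_dir / "truth"
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    report: dict = {"seed": config.seed}
    t0 = time.time()

    # --- simulate ---------------------------------------------------------
    features, bgcs, truth = simulate_bgc_universe(sim)
    reference = simulate_reference_db(truth, sim)
    genomes, ani, species_truth = simulate_genome_collection(sim)
    from .io import write_features_long

    paths = [
        write_tsv(bgcs, out_dir / "bgcs.tsv"),
        write_features_long(features, out_dir / "bgc_features.tsv"),
        write_features_long(reference, out_dir / "reference_features.tsv", id_name="ref_id"),
        write_tsv(genomes, out_dir / "genomes.tsv"),
        write_matrix(ani, out_dir / "ani.tsv"),
        write_tsv(truth.bgc_truth, truth_dir / "bgc_truth.tsv"),
        write_tsv(species_truth, truth_dir / "species_truth.tsv"),
    ]
    write_json(dataclasses.asdict(sim), truth_dir / "simulation_config.json")
    _manifest(out_dir, "simulate", dataclasses.asdict(sim), paths, config.seed)

    # --- genome qc --------------------------------------------------------
    summaries = genome_qc.summarize_genomes(genomes)
    clusters = genome_qc.cluster_species(ani, threshold=config.ani_threshold)
    reps = {
        sp: genome_qc.select_representative(grp["genome_id"], summaries)
        for sp, grp in clusters.groupby("species_id")
    }
    clusters["representative_id"] = clusters["species_id"].map(reps)
    paths = [
        write_tsv(summaries, out_dir / "genome_quality.tsv"),
        write_tsv(clusters, out_dir / "species_clusters.tsv"),
    ]
    _manifest(out_dir, "qc", {"ani_threshold": config.ani_threshold}, paths, config.seed)
    report["n_genomes"] = int(len(genomes))
    report["n_genomes_retained"] = int(summaries["retained"].sum())
    report["n_species"] = int(clusters["species_id"].nunique())

    # --- bgc families -----------------------------------------------------
    filtered = bgc_families.filter_bgcs(bgcs, min_scaffold_bp=config.scaffold_min_bp)
    assignment = bgc_families.cluster_families(
        features.loc[filtered["bgc_id"]], t_gcf=config.t_gcf, t_gcc=config.t_gcc
    )
    rep_bgcs = bgc_families.dereplicate_bgcs(assignment, filtered)
    out_assign = assignment.assignments.copy()
    out_assign["representative"] = out_assign["bgc_id"].isin(rep_bgcs)
    linkage_df = pd.DataFrame(
        assignment.linkage_tree, columns=["left", "right", "height", "size"]
    )
    paths = [
        write_tsv(out_assign, out_dir / "gcf_assignments.tsv"),
        write_tsv(linkage_df, out_dir / "linkage.tsv"),
    ]
    _manifest(
        out_dir, "cluster_bgcs",
        {"t_gcf": config.t_gcf, "t_gcc": config.t_gcc,
         "scaffold_min_bp": config.scaffold_min_bp},
        paths, config.seed,
    )
    report["n_bgcs"] = int(len(bgcs))
    report["n_bgcs_filtered"] = int(len(filtered))
    report["n_gcfs"] = assignment.n_gcfs
    report["n_gccs"] = assignment.n_gccs
    report["n_representative_bgcs"] = len(rep_bgcs)

    # --- novelty ----------------------------------------------------------
    d_min = novelty.min_distances(features.loc[filtered["bgc_id"]], reference)
    fam_table = novelty.family_novelty_table(d_min, assignment.assignments, rep_bgcs)
    gcf_rows = fam_table[fam_table["level"] == "GCF"]
    gcc_rows = fam_table[fam_table["level"] == "GCC"]
    novel_gcfs = novelty.novelty_summary(int(gcf_rows["flagged"].sum()), len(gcf_rows))
    remote_gccs = novelty.novelty_summary(int(gcc_rows["flagged"].sum()), len(gcc_rows))
    paths = [
        write_tsv(d_min.rename("d_min").reset_index(), out_dir / "novelty_bgc.tsv"),
        write_tsv(fam_table, out_dir / "novelty_family.tsv"),
        write_json({"novel_gcfs": novel_gcfs, "remote_gccs": remote_gccs},
                   out_dir / "novelty_summary.json"),
    ]
    _manifest(out_dir, "novelty",
              {"gcf_threshold": config.novelty_gcf, "gcc_threshold": config.novelty_gcc},
              paths, config.seed)
    report["novel_gcfs"] = novel_gcfs
    report["remote_gccs"] = remote_gccs

    # --- profiling --------------------------------------------------------
    if config.run_profiling:
        profiles = simulate_profiles(sim, bgcs, truth)
        gene_lengths = profiles.genes.set_index("gene_id")["gene_len_bp"]
        gcf_of = assignment.assignments.set_index("bgc_id")["gcf"]
        genes_of_bgc = {
            row["bgc_id"]: str(row["biosynthetic_gene_ids"]).split(";")
            for _, row in filtered.iterrows()
        }
        normalizers = profiles.markers.groupby("sample_id")["abundance"].sum()
        fam_rows = {}
        sample_ids = list(profiles.samples["sample_id"])
        for sample_id, sample_aln in profiles.alignments.groupby("sample_id"):
            kept = profiling.filter_alignments(sample_aln, preset="gene")
            counts = profiling.assign_inserts(kept)
            gene_ab = profiling.length_normalize(counts, gene_lengths)
            per_family: dict = {}
            for bgc_id in rep_bgcs:
                ab = profiling.bgc_abundance(gene_ab, genes_of_bgc[bgc_id])
                fam = gcf_of[bgc_id]
                per_family.setdefault(fam, []).append(ab)
            fam_rows[sample_id] = {
                fam: profiling.cell_normalize(
                    profiling.family_abundance(v), normalizers.get(sample_id, 0.0)
                )
                for fam, v in per_family.items()
            }
        fam_matrix = (
            pd.DataFrame.from_dict(fam_rows, orient="index")
            .reindex(sample_ids)
            .fillna(0.0)
            .sort_index(axis=1)
        )
        fam_matrix.index.name = "sample_id"
        prev = fam_matrix.apply(profiling.prevalence, axis=0).rename("prevalence_pct")
        paths = [
            write_matrix(fam_matrix, out_dir / "family_abundance.tsv"),
            write_tsv(prev.reset_index().rename(columns={"index": "gcf"}),
                      out_dir / "prevalence.tsv"),
        ]
        _manifest(out_dir, "profile", {"preset": "gene"}, paths, config.seed)
        report["prevalence_quantiles"] = {
            q: float(np.quantile(prev, float(q))) for q in ("0.25", "0.5", "0.75")
        }
    else:
        report["profiling"] = "disabled"

    # --- community structure ---------------------------------------------
    if config.run_structure and config.run_profiling:
        distances = community.sample_distances(fam_matrix)
        embedding = community.embed_samples(fam_matrix, seed=config.seed)
        size, labels, probs = community.choose_min_cluster_size(embedding)
        clustered = labels != -1
        perm = {"pseudo_F": None, "p_value": None, "groups": "planted"}
        f_stat, p_value = community.permanova(
            distances, profiles.samples["true_community_type"].to_numpy(),
            n_permutations=config.n_permutations, seed=config.seed,
        )
        perm = {
            "pseudo_F": f_stat, "p_value": p_value,
            "n_permutations": config.n_permutations, "groups": "planted",
        }
        types_df = profiles.samples[["sample_id", "true_community_type"]].copy()
        types_df["cluster"] = labels
        types_df["membership_probability"] = probs
        paths = [
            write_tsv(types_df, out_dir / "community_types.tsv"),
            write_json(perm, out_dir / "permanova.json"),
        ]
        species_div = _species_biosynthesis(filtered, config.bgc_rich_floor)
        paths.append(write_tsv(species_div, out_dir / "species_biosynthesis.tsv"))
        _manifest(out_dir, "structure",
                  {"min_cluster_size": int(size),
                   "n_permutations": config.n_permutations},
                  paths, config.seed)
        report["permanova"] = perm
        report["n_community_clusters"] = int(len(set(labels[clustered])))
    report["runtime_s"] = round(time.time() - t0, 2)
    write_json(report, out_dir / "report.json")
    return report


def _species_biosynthesis(filtered_bgcs: pd.DataFrame, rich_floor: int) -> pd.DataFrame:
    """Per-species BGC counts, richness flags and product-type diversity."""
    binned = filtered_bgcs[filtered_bgcs["genome_id"].astype(str).str.len() > 0]
    if binned.empty:
        return pd.DataFrame(
            columns=["species_id", "representative_genome",
                     "max_bgcs_per_genome", "bgc_rich", "shannon_H"]
        )
    counts = (
        binned.groupby(["species_id", "genome_id"]).size().rename("n_bgcs").reset_index()
    )
    flags = community.flag_bgc_rich(counts, floor=rich_floor)
    shannon = {}
    for species, grp in binned.groupby("species_id"):
        keys = [
            bgc_families.product_type_key(str(p).split(";"))
            for p in grp["product_types"]
        ]
        shannon[species] = community.shannon_product_diversity(
            pd.Series(keys).value_counts().to_numpy()
        )
    flags["shannon_H"] = flags["species_id"].map(shannon)
    return flags


def render_summary(report: dict) -> str:
    """Human-readable summary with "count (percent%)" phrasing."""
    lines = [f"seascape pipeline report (seed {report.get('seed')})"]
    if "n_genomes" in report:
        lines.append(
            f"genomes: {report['n_genomes']:,} "
            f"({report['n_genomes_retained']:,} retained), "
            f"{report['n_species']:,} species"
        )
    if "n_bgcs" in report:
        lines.append(
            f"BGCs: {report['n_bgcs']:,} ({report['n_bgcs_filtered']:,} on >=5 kb "
            f"scaffolds) -> {report['n_gcfs']:,} GCFs, {report['n_gccs']:,} GCCs"
        )
    for key, label in (("novel_gcfs", "novel GCFs"), ("remote_gccs", "remote GCCs")):
        if key in report:
            lines.append(f"{label}: {format_count_percent(report[key])}")
    if "permanova" in report and report["permanova"].get("p_value") is not None:
        p = report["permanova"]
        lines.append(f"PERMANOVA: pseudo-F = {p['pseudo_F']:.3g}, p = {p['p_value']:.4g}")
    return "\n".join(lines)


def format_count_percent(summary: dict) -> str:
    """Render one novelty summary as e.g. ``3,012 (78%)``."""
    return f"{summary['count']:,} ({summary['percent']}%)"
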