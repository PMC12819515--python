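"""End-to-end orchestration of the super-enhancer / CRC / MTF analysis.

``run_all`` drives every stage over a dataset directory described by a
sample sheet: per-sample super-enhancer calling, consensus matrix and
PCA, GGAA-microsatellite statistics with the paired SE-vs-enhancer
Wilcoxon test, per-sample CRC clique inference with the cross-entity
specificity filter, promoter-enhancer chain traversal, the 2-of-3
criteria integration, fusion-TF colocalization over the top SEs, and the
SE/dependency overlap summary. Each stage reads and writes plain files;
there is no hidden state, so a rerun with the same config is
bit-identical for the deterministic stages (all of them).

Every numeric constant of the analysis is surfaced as a named parameter
with its standard value as default: 12.5 kb stitching, top 500 SEs, 50%
SE merge overlap, >= 4 consecutive GGAA, top 10 CRC cliques, >= 50% case
/ < 30% control specificity, 5-interaction chain depth, 2-of-3 MTF
criteria, top 100 SEs for colocalization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import RegionSet, read_regions, read_signal, read_bedpe, write_regions
from .motifs import read_jaspar
from .tables import ExpressionTable, read_expression, read_dependency
from . import superenhancers as se
from . import microsatellites as ms
from . import circuitry as crc
from . import chains as ch
from . import selection as sel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Paths plus every tunable parameter of the analysis."""

    dataset_dir: str
    sample_sheet: str = "sample_sheet.tsv"
    genome: str = "genome.fa"
    genes: str = "genes.bed"
    tf_list: str = "tf_list.txt"
    motifs: str = "motifs.jaspar"
    expression: str = "expression.tsv"
    dependency: str = "dependency.csv"
    # super-enhancer calling
    stitch_distance: int = 12_500
    tss_exclusion: int = 2_500
    use_tss_exclusion: bool = False
    top_n_se: int = 500
    consensus_min_overlap: float = 0.5
    consensus_mode: str = "of_smaller"
    # microsatellites
    msat_k_specs: tuple[tuple[int, int], ...] = ((4, 4), (3, 5))
    ggaa_min_repeats: int = 4
    ggaa_mode: str = "rotation+rc"
    # CRC
    activity_threshold: float = 1.0
    score_fraction: float = 0.85
    crc_top_k: int = 10
    case_min: float = 0.5
    control_max: float = 0.3
    # chains / selection
    chain_max_depth: int = 5
    min_criteria: int = 2
    coloc_top_n: int = 100
    lineage: str = "case"
    seed: int = 0

    def path(self, name: str) -> Path:
        return Path(self.dataset_dir) / name

    def validate(self) -> None:
        for attr in ("sample_sheet", "genome", "genes", "tf_list", "motifs",
                     "expression", "dependency"):
            p = self.path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"missing input file: {p}")


def load_gene_models(genes_path: Path, tf_list_path: Path) -> list[crc.GeneModel]:
    tf_set = {line.strip() for line in open(tf_list_path) if line.strip()}
    regions = read_regions(genes_path, "bed6")
    return [
        crc.GeneModel(r.name, r, is_tf=r.name in tf_set)
        for r in regions
    ]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        wrapped.__name__ = fn.__name__
        return wrapped
    return deco


@dataclass
class _Study:
    """Loaded inputs shared by the stages."""

    config: PipelineConfig
    sheet: pd.DataFrame
    genome: object
    gene_models: list
    motifs_by_tf: dict
    expression: ExpressionTable
    dependency: pd.DataFrame

    @property
    def case_ids(self) -> list[str]:
        return list(self.sheet.loc[self.sheet["group"] == "case", "sample_id"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.sheet.loc[self.sheet["group"] == "control", "sample_id"])


def load_study(config: PipelineConfig) -> _Study:
    import pyfaidx

    config.validate()
    sheet = pd.read_csv(config.path(config.sample_sheet), sep="\t",
                        keep_default_na=False, dtype=str)
    required = {"sample_id", "group", "peaks", "signal"}
    if not required <= set(sheet.columns):
        raise ValueError(
            f"sample sheet missing columns {sorted(required - set(sheet.columns))}"
        )
    genome = pyfaidx.Fasta(str(config.path(config.genome)))
    gene_models = load_gene_models(config.path(config.genes),
                                   config.path(config.tf_list))
    motifs_by_tf: dict[str, list] = {}
    for motif in read_jaspar(config.path(config.motifs)):
        motifs_by_tf.setdefault(motif.tf_name, []).append(motif)
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    expression = read_expression(config.path(config.expression), groups)
    dependency = read_dependency(config.path(config.dependency))
    return _Study(config, sheet, genome, gene_models, motifs_by_tf,
                  expression, dependency)


@_stage("se_calling")
def stage_se_calling(study: _Study) -> dict[str, se.RankedProfile]:
    cfg = study.config
    tss_excl = None
    if cfg.use_tss_exclusion:
        tss_regions = []
        for gm in study.gene_models:
            start = max(0, gm.tss.start - cfg.tss_exclusion)
            tss_regions.append(
                gm.tss.__class__(gm.tss.chrom, start,
                                 gm.tss.start + cfg.tss_exclusion + 1)
            )
        tss_excl = RegionSet(tss_regions)
    profiles: dict[str, se.RankedProfile] = {}
    for row in study.sheet.itertuples():
        peaks = read_regions(cfg.path(row.peaks), "narrowPeak",
                             sample_id=row.sample_id)
        signal = read_signal(cfg.path(row.signal))
        control = None
        if getattr(row, "control_signal", ""):
            control = read_signal(cfg.path(row.control_signal))
        stitched = se.stitch_peaks(peaks, cfg.stitch_distance, tss_excl)
        scored = se.score_regions(stitched, signal, control)
        profile = se.call_superenhancers(scored, sample_id=row.sample_id)
        profiles[row.sample_id] = se.normalize_profile(profile, cfg.top_n_se)
    return profiles


@_stage("consensus_pca")
def stage_consensus(study: _Study, profiles: dict[str, se.RankedProfile]):
    cfg = study.config
    ordered = [profiles[s] for s in study.sheet["sample_id"]]
    matrix = se.build_consensus(ordered, cfg.consensus_min_overlap,
                                cfg.consensus_mode)
    n_comp = min(2, len(matrix.samples), len(matrix.consensus_regions))
    scores, evr = se.pca_profiles(matrix, n_components=n_comp)
    return matrix, scores, evr


@_stage("msat_enrichment")
def stage_msat(study: _Study, profiles: dict[str, se.RankedProfile]):
    cfg = study.config
    classes = ms.ggaa_classes(cfg.ggaa_mode)
    per_sample = {}
    se_means, enh_means = [], []
    for sample_id in study.case_ids:
        profile = profiles[sample_id]
        se_regions = RegionSet(
            [sr.region for sr in profile.superenhancers()], sample_id)
        enh_regions = RegionSet(
            [sr.region for sr, flag in zip(profile.regions, profile.se_flags)
             if not flag], sample_id)
        se_stats = ms.count_msats_in_regions(se_regions, study.genome,
                                             classes, label="SE")
        enh_stats = ms.count_msats_in_regions(enh_regions, study.genome,
                                              classes, label="enhancer")
        per_sample[sample_id] = (se_stats, enh_stats)
        se_means.append(se_stats.mean_normalized)
        enh_means.append(enh_stats.mean_normalized)
    try:
        statistic, p_value, n_pairs = ms.paired_enrichment_test(se_means, enh_means)
    except ValueError as exc:
        # fewer than 5 usable pairs: the paired test is not computable for
        # this cohort size; the per-sample densities are still reported
        logger.warning("paired enrichment test unavailable: %s", exc)
        statistic, p_value, n_pairs = None, None, 0
    # pooled fractions of regions containing >= 1 mSat
    all_se = [sr.region for s in study.case_ids
              for sr in profiles[s].superenhancers()]
    all_enh = [sr.region for s in study.case_ids
               for sr, f in zip(profiles[s].regions, profiles[s].se_flags)
               if not f]
    frac_se = ms.fraction_with_msat(RegionSet(all_se), study.genome, classes)
    frac_enh = ms.fraction_with_msat(RegionSet(all_enh), study.genome, classes)
    return {
        "per_sample": per_sample,
        "se_means": se_means,
        "enhancer_means": enh_means,
        "wilcoxon_statistic": statistic,
        "wilcoxon_p": p_value,
        "n_pairs": n_pairs,
        "pct_se_with_msat": frac_se,
        "pct_enhancer_with_msat": frac_enh,
    }


@_stage("ets_msat_peaks")
def stage_ets(study: _Study) -> dict[str, RegionSet]:
    """Flagged fusion-TF mSat peaks per sample (samples with ETS data)."""
    cfg = study.config
    flagged: dict[str, RegionSet] = {}
    for row in study.sheet.itertuples():
        path = getattr(row, "ets_peaks", "")
        if not path:
            continue
        peaks = read_regions(cfg.path(path), "narrowPeak", sample_id=row.sample_id)
        flags = ms.flag_msat_peaks(peaks, study.genome, cfg.ggaa_mode)
        flagged[row.sample_id] = RegionSet(
            [p for p, f in zip(peaks, flags) if f], row.sample_id)
    return flagged


@_stage("crc_inference")
def stage_crc(study: _Study, profiles: dict[str, se.RankedProfile]):
    cfg = study.config
    cliques_by_sample = {}
    assignments_by_sample = {}
    for sample_id in study.sheet["sample_id"]:
        profile = profiles[sample_id]
        active = crc.active_genes(study.expression, sample_id,
                                  cfg.activity_threshold)
        active_models = [g for g in study.gene_models if g.gene in active]
        assignments = []
        for sr in profile.superenhancers():
            a = crc.assign_se_to_gene(sr.region, active_models)
            if a is not None:
                assignments.append((a, sr))
        assignments_by_sample[sample_id] = [a for a, _ in assignments]
        tf_constituents: dict[str, list] = {}
        tf_flags = {g.gene: g.is_tf for g in study.gene_models}
        for a, sr in assignments:
            if tf_flags.get(a.assigned_gene):
                tf_constituents.setdefault(a.assigned_gene, []).extend(
                    sr.constituents)
        net = crc.build_tf_network(sample_id, tf_constituents, study.genome,
                                   study.motifs_by_tf, cfg.score_fraction)
        cliques_by_sample[sample_id] = crc.find_crc_cliques(net, cfg.crc_top_k)
    membership = crc.crc_membership(cliques_by_sample)
    # ensure every sample appears as a column even without cliques
    for sample_id in study.sheet["sample_id"]:
        if sample_id not in membership.columns:
            membership[sample_id] = False
    membership = membership[sorted(membership.columns)]
    if not study.case_ids or not study.control_ids:
        raise ValueError("specificity filter needs non-empty case and control groups")
    specificity = crc.specificity_filter(
        membership, study.case_ids, study.control_ids,
        cfg.case_min, cfg.control_max)
    return cliques_by_sample, assignments_by_sample, membership, specificity


@_stage("pe_chains")
def stage_chains(study: _Study, ets_flagged: dict[str, RegionSet],
                 tfs: list[str]) -> pd.DataFrame:
    cfg = study.config
    rows = {}
    for row in study.sheet.itertuples():
        loops_path = getattr(row, "loops", "")
        if not loops_path:
            continue
        loops = read_bedpe(cfg.path(loops_path))
        peaks = read_regions(cfg.path(row.peaks), "narrowPeak",
                             sample_id=row.sample_id)
        graph = ch.build_anchor_graph(
            loops, study.gene_models, peaks,
            ets_flagged.get(row.sample_id),
        )
        rows[row.sample_id] = ch.chain_table(graph, tfs, cfg.chain_max_depth)
    table = pd.DataFrame(rows)  # TF x sample, NaN = unreached
    return table.reindex(tfs)


@_stage("mtf_selection")
def stage_selection(study: _Study, profiles, assignments_by_sample,
                    ets_flagged, candidates: list[str]):
    cfg = study.config
    dep_genes = sel.dependency_filter(study.dependency, cfg.lineage)
    flags = []
    for tf in sorted(candidates):
        counts: list[float | None] = []
        for sample_id in study.case_ids:
            se_regions = [a.se_region for a in assignments_by_sample[sample_id]
                          if a.assigned_gene == tf]
            if not se_regions:
                counts.append(None)
                continue
            flagged = ets_flagged.get(sample_id)
            n = 0
            if flagged is not None:
                n = sum(
                    1 for p in flagged
                    if any(p.overlaps(r) for r in se_regions)
                )
            counts.append(float(n))
        flags.append(sel.CriterionFlags(
            tf,
            msat_in_se=sel.msat_in_se_criterion(tf, counts),
            specific_expression=sel.expression_specificity(
                study.expression, tf, study.case_ids, study.control_ids),
            depmap_dependency=tf in dep_genes,
        ))
    selected = sel.select_mtfs(flags, cfg.min_criteria)
    se_assigned = [a.assigned_gene
                   for s in study.case_ids
                   for a in assignments_by_sample[s]]
    overlap = sel.se_dependency_overlap(dep_genes, se_assigned)
    return selected, dep_genes, overlap


@_stage("colocalization")
def stage_colocalization(study: _Study, matrix: se.ConsensusMatrix,
                         peak_sets: dict[str, RegionSet]):
    cfg = study.config
    case_cols = [matrix.samples.index(s) for s in study.case_ids
                 if s in matrix.samples]
    mean_int = matrix.values[:, case_cols].mean(axis=1)
    order = np.argsort(-mean_int, kind="stable")
    top = [matrix.consensus_regions[i]
           for i in order[:cfg.coloc_top_n]]
    return sel.colocalization_top_se(top, peak_sets)


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage; write per-stage tables and a summary to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = load_study(config)

    profiles = stage_se_calling(study)
    se_dir = out / "se_calls"
    se_dir.mkdir(exist_ok=True)
    for sample_id, profile in profiles.items():
        rows = []
        n = len(profile.regions)
        for rank, (sr, flag, x) in enumerate(
                zip(profile.regions, profile.se_flags,
                    profile.normalized_intensity), start=1):
            rows.append({
                "chrom": sr.region.chrom, "start": sr.region.start,
                "end": sr.region.end, "n_constituents": len(sr.constituents),
                "net_signal": sr.net_signal, "rank": n - rank + 1,
                "normalized_intensity": x, "is_super": int(flag),
            })
        pd.DataFrame(rows).to_csv(se_dir / f"{sample_id}.tsv", sep="\t",
                                  index=False)
        write_regions(
            [sr.region for sr in profile.superenhancers()],
            se_dir / f"{sample_id}.se.bed", "bed3")

    matrix, scores, evr = stage_consensus(study, profiles)
    region_labels = [str(r) for r in matrix.consensus_regions]
    pd.DataFrame(matrix.values, index=region_labels,
                 columns=matrix.samples).to_csv(
        out / "consensus_matrix.tsv", sep="\t", index_label="region")
    pc_cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    pd.DataFrame(scores, index=matrix.samples, columns=pc_cols).to_csv(
        out / "pca_scores.tsv", sep="\t", index_label="sample")
    case_regions, case_curve = se.se_rank_curve(matrix, study.case_ids)
    pd.DataFrame({
        "rank": np.arange(1, len(case_curve) + 1),
        "region": [str(r) for r in case_regions],
        "mean_normalized_signal": case_curve,
    }).to_csv(out / "se_rank_curve_case.tsv", sep="\t", index=False)

    msat = stage_msat(study, profiles)
    pd.DataFrame({
        "sample_id": study.case_ids,
        "se_mean_per_kb": msat["se_means"],
        "enhancer_mean_per_kb": msat["enhancer_means"],
    }).to_csv(out / "msat_stats.tsv", sep="\t", index=False)

    ets_flagged = stage_ets(study)
    cliques_by_sample, assignments, membership, specificity = \
        stage_crc(study, profiles)
    membership.astype(int).to_csv(out / "crc_membership.tsv", sep="\t",
                                  index_label="tf")
    pd.DataFrame([asdict(s) for s in specificity]).to_csv(
        out / "specificity.tsv", sep="\t", index=False)
    with open(out / "cliques.json", "w") as fh:
        json.dump({
            sample: [{"tfs": list(c.tf_set), "score": c.score, "rank": c.rank}
                     for c in cliques]
            for sample, cliques in cliques_by_sample.items()
        }, fh, indent=1, sort_keys=True)
        fh.write("\n")

    candidates = [s.tf for s in specificity if s.is_candidate]
    all_tfs = sorted(g.gene for g in study.gene_models if g.is_tf)
    chain_tbl = stage_chains(study, ets_flagged, all_tfs)
    chain_tbl.to_csv(out / "chain_table.tsv", sep="\t", index_label="tf")

    selected, dep_genes, overlap = stage_selection(
        study, profiles, assignments, ets_flagged, candidates)
    pd.DataFrame([
        {"tf": c.tf, "msat_in_se": c.flags.msat_in_se,
         "specific_expression": c.flags.specific_expression,
         "depmap_dependency": c.flags.depmap_dependency,
         "n_criteria": c.n_criteria, "selected": c.selected}
        for c in selected
    ]).to_csv(out / "mtf_criteria.tsv", sep="\t", index=False)

    histogram, fraction_all = stage_colocalization(study, matrix, ets_flagged)
    pd.DataFrame({
        "n_cobound": list(histogram),
        "n_se": list(histogram.values()),
    }).to_csv(out / "colocalization.tsv", sep="\t", index=False)

    lineage_rows = study.dependency[
        study.dependency["lineage"] == config.lineage]
    top_dep = lineage_rows.sort_values("t_statistic").iloc[0]["gene"]
    crc_members = set(membership.index[membership.any(axis=1)])
    summary = {
        "version": __version__,
        "parameters": asdict(config),
        "n_samples": int(len(study.sheet)),
        "n_consensus_se": len(matrix.consensus_regions),
        "pca_explained_variance_ratio": [float(v) for v in evr],
        "msat_wilcoxon_p": msat["wilcoxon_p"],
        "pct_se_with_msat": msat["pct_se_with_msat"],
        "pct_enhancer_with_msat": msat["pct_enhancer_with_msat"],
        "specificity_candidates": candidates,
        "selected_mtfs": [c.tf for c in selected if c.selected],
        "n_dependency_genes": overlap.n_dependency_genes,
        "n_dependency_se_associated": overlap.n_se_associated,
        "dependency_se_fraction": overlap.fraction,
        "top_dependency": str(top_dep),
        "top_dependency_in_crc": bool(top_dep in crc_members),
        "coloc_fraction_all_bound": fraction_all,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
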