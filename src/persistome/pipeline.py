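"""End-to-end orchestration of the synthetic two-omics persistence study.

``run_pipeline`` generates the paired-design datasets, runs differential
methylation and expression per arm and timepoint, integrates the layers,
partitions calls by persistence, runs enrichment, and writes every table
of the bundle plus a machine-readable summary.  All randomness derives
from the single configured seed, and the configuration hash is stamped
into the bundle so identical reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import integration as integ
from . import io as pio
from . import methylome as meth
from . import report as rep
from . import stats
from . import synthetic as syn
from . import transcriptome as rna
from .config import AnalysisConfig

log = logging.getLogger("persistome")

__all__ = ["StudyData", "simulate_study", "run_pipeline", "derive_seed", "score_recovery"]


def derive_seed(base: int, stream: int) -> int:
    """Independent child seed (< 2^31) for one named random stream."""
    return int(np.random.SeedSequence([int(base), int(stream)]).generate_state(1)[0] % (2**31))


@dataclass
class StudyData:
    """One simulated study: design, annotations, both omics layers, truth."""

    sheet: pd.DataFrame
    manifest: pd.DataFrame
    beta: syn.BetaMatrix
    counts: pd.DataFrame
    registry: syn.TruthRegistry


def simulate_study(config: AnalysisConfig, seed: int | None = None) -> StudyData:
    """Generate the full synthetic study described by the configuration."""
    base = config.seed if seed is None else seed
    sim = config.simulation
    sheet = syn.generate_design(sim.n_lines, sim.arms, sim.timepoints, derive_seed(base, 0))
    manifest = syn.generate_probe_manifest(
        sim.n_genes, sim.probes_per_gene, sim.frac_intergenic, derive_seed(base, 1)
    )

    diametral = syn.TruthRegistry()
    used_genes: set = set()
    for i, (arm, n) in enumerate(sorted(sim.diametral.items())):
        cfg = config.diametral_cfg(arm)
        candidates = manifest[~manifest["gene"].isin(used_genes)]
        fragment = syn.plant_diametral_genes(n, candidates, cfg, derive_seed(base, 2 + i))
        used_genes |= set(fragment.diametral_genes())
        diametral.extend(fragment)

    genes = list(dict.fromkeys(manifest.loc[manifest["gene"] != "", "gene"]))
    counts, expr_registry = syn.simulate_transcriptome(
        genes, sheet, sim.expression, derive_seed(base, 11), extra_truth=diametral
    )
    # Keep the truth clean: promoter probes of genes with planted expression
    # effects never receive an independent methylation effect, so the only
    # diametral pairs in the data are the tagged ones.
    expr_genes = expr_registry.feature_ids(layer="expression")
    promoter_probes_of_expr = frozenset(
        manifest.loc[
            manifest["gene"].isin(expr_genes)
            & manifest["region_class"].isin(syn.PROMOTER_REGIONS),
            "probe_id",
        ]
    )
    beta, meth_registry = syn.simulate_methylome(
        manifest,
        sheet,
        sim.methyl,
        derive_seed(base, 10),
        extra_truth=diametral,
        avoid_probes=promoter_probes_of_expr - diametral.feature_ids(layer="methylation"),
    )
    registry = syn.TruthRegistry()
    registry.extend(meth_registry)
    registry.extend(expr_registry)
    return StudyData(sheet=sheet, manifest=manifest, beta=beta, counts=counts, registry=registry)


def score_recovery(truth_set: frozenset, recovered: frozenset) -> dict:
    """Sensitivity/precision of a recovered feature set against planted truth."""
    tp = len(truth_set & recovered)
    sens = tp / len(truth_set) if truth_set else float("nan")
    prec = tp / len(recovered) if recovered else (1.0 if not truth_set else 0.0)
    return {
        "n_truth": len(truth_set),
        "n_recovered": len(recovered),
        "n_true_positive": tp,
        "sensitivity": sens,
        "precision": prec,
    }


def _partition_frame(part: integ.PersistencePartition) -> pd.DataFrame:
    rows = []
    for status, features in (
        ("stable_up", part.stable_up),
        ("stable_down", part.stable_down),
        ("transient", part.transient),
        ("flipped", part.flipped),
    ):
        for f in sorted(features):
            rows.append({"feature_id": f, "status": status})
    return pd.DataFrame(rows, columns=["feature_id", "status"])


def run_pipeline(config: AnalysisConfig, outdir, seed: int | None = None) -> dict:
    """Execute the full analysis and write the output bundle to ``outdir``."""
    base = config.seed if seed is None else seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.touch()

    summary: dict = {"config_hash": config.config_hash(), "seed": base, "arms": {}}
    files: list[str] = []

    def save(name: str, writer) -> None:
        writer(out / name)
        files.append(name)

    log.info("simulating study (seed %d)", base)
    study = simulate_study(config, base)
    sim = config.simulation
    save("config.yaml", config.to_yaml)
    save("sample_sheet.tsv", lambda p: pio.write_sample_sheet(study.sheet, p))
    save("probe_manifest.tsv", lambda p: pio.write_manifest(study.manifest, p))
    save("beta.tsv", lambda p: pio.write_matrix(study.beta.values, p))
    save("detection_p.tsv", lambda p: pio.write_matrix(study.beta.detection_p, p))
    save("counts.tsv", lambda p: pio.write_matrix(study.counts, p))
    save("truth_registry.json", study.registry.to_json)

    # Symbol reconciliation between the count matrix and the manifest.
    manifest_genes = set(study.manifest.loc[study.manifest["gene"] != "", "gene"])
    count_genes = set(study.counts.index)
    save(
        "gene_reconciliation.json",
        lambda p: Path(p).write_text(
            json.dumps(
                {
                    "n_shared": len(manifest_genes & count_genes),
                    "counts_only": sorted(count_genes - manifest_genes),
                    "manifest_only": sorted(manifest_genes - count_genes),
                },
                indent=1,
            )
        ),
    )

    arms = [a for a in sim.arms if a != "MOCK"]
    timepoints = list(sim.timepoints)
    filter_report = None
    venn: dict = {}

    # PCA across all samples on the expression layer.
    kept_all = rna.filter_low_expression(study.counts, study.sheet)
    factors_all = rna.tmm_normalize(kept_all)
    logcpm_all = rna.log_cpm(kept_all, factors_all)
    pca = rna.pca_top_features(logcpm_all, min(config.pca_top_n, logcpm_all.shape[0]))
    save("pca_scores.tsv", lambda p: pca.scores.to_csv(p, sep="\t"))
    summary["pca_variance_fraction"] = [float(v) for v in pca.variance_fraction[:5]]
    save("norm_factors.tsv", lambda p: factors_all.to_frame().to_csv(p, sep="\t", index=False))

    for arm in arms:
        arm_summary: dict = {"timepoints": {}}
        dmc_calls: dict = {}
        deg_calls: dict = {}
        integ_tables: dict = {}
        de_tables: dict = {}

        for tp in timepoints:
            log.info("differential methylation: %s at %s", arm, tp)
            dm_table, f_report = meth.dm_pipeline(
                study.beta,
                study.sheet,
                arm,
                tp,
                manifest=study.manifest,
                detection_threshold=config.detection_threshold,
                detection_rule=config.detection_rule,
                normalize_scale=config.normalize_scale,
            )
            filter_report = f_report
            save(f"dm_{arm}_{tp}.tsv", lambda p, t=dm_table: pio.write_diff_table(t, p))
            calls_m = stats.call_features(dm_table, config.p_max, config.min_fold)
            dmc_calls[tp] = calls_m

            dist = meth.region_distribution(calls_m, study.manifest)
            dist_frame = pd.concat(
                [dist.regions.assign(kind="region"), dist.islands.assign(kind="island")]
            )
            save(
                f"dmc_distribution_{arm}_{tp}.tsv",
                lambda p, t=dist_frame: t.to_csv(p, sep="\t", index=False),
            )

            log.info("differential expression: %s at %s", arm, tp)
            de_table = rna.de_pipeline(study.counts, study.sheet, arm, tp)
            de_tables[tp] = de_table
            save(f"de_{arm}_{tp}.tsv", lambda p, t=de_table: pio.write_diff_table(t, p))
            calls_e = stats.call_features(de_table, config.p_max, config.min_fold)
            deg_calls[tp] = calls_e

            pmap = integ.map_promoter_dmcs(calls_m, study.manifest)
            table = integ.diametral_overlap(calls_e, pmap)
            integ_tables[tp] = table
            save(
                f"integration_{arm}_{tp}.tsv",
                lambda p, t=table: t.to_csv(p, sep="\t", index=False),
            )

            venn.setdefault(arm, {})[tp] = {
                "n_deg_genes": calls_e.total,
                "n_promoter_dmc_genes": len(pmap.genes),
                "n_overlap_genes": int(len(table)),
                "n_diametral_up": int((table["class"] == "diametral_up").sum()),
                "n_diametral_down": int((table["class"] == "diametral_down").sum()),
                "n_conflicting": int((table["class"] == "conflicting").sum()),
            }
            arm_summary["timepoints"][tp] = {
                "dmc": rep.summarize_calls(calls_m, n_tested=len(dm_table)),
                "deg": rep.summarize_calls(calls_e, n_tested=len(de_table)),
                "promoter_dmc_assignments": pmap.n_assignments,
            }

        t1, t2 = timepoints[0], timepoints[-1]
        part_expr = integ.persistence_partition(deg_calls[t1], deg_calls[t2], (t1, t2))
        part_meth = integ.persistence_partition(dmc_calls[t1], dmc_calls[t2], (t1, t2))
        save(
            f"persistence_expression_{arm}.tsv",
            lambda p, t=_partition_frame(part_expr): t.to_csv(p, sep="\t", index=False),
        )
        save(
            f"persistence_methylation_{arm}.tsv",
            lambda p, t=_partition_frame(part_meth): t.to_csv(p, sep="\t", index=False),
        )
        stable_up, stable_down = integ.stable_diametral_genes(integ_tables[t1], integ_tables[t2])
        save(
            f"stable_diametral_{arm}.txt",
            lambda p, g=stable_up | stable_down: pio.write_gene_list(g, p),
        )
        venn[arm]["stable"] = {
            "n_stable_up_deg": len(part_expr.stable_up),
            "n_stable_down_deg": len(part_expr.stable_down),
            "n_stable_diametral_up": len(stable_up),
            "n_stable_diametral_down": len(stable_down),
            "stable_diametral_up": sorted(stable_up),
            "stable_diametral_down": sorted(stable_down),
        }
        arm_summary["persistence"] = {
            "expression": {
                "stable_up": len(part_expr.stable_up),
                "stable_down": len(part_expr.stable_down),
                "transient": len(part_expr.transient),
                "flipped": len(part_expr.flipped),
            },
            "methylation": {
                "stable_up": len(part_meth.stable_up),
                "stable_down": len(part_meth.stable_down),
                "transient": len(part_meth.transient),
                "flipped": len(part_meth.flipped),
            },
        }
        arm_summary["stable_diametral"] = {
            "up": sorted(stable_up),
            "down": sorted(stable_down),
        }
        arm_summary["recovery"] = {
            "stable_diametral_up": score_recovery(
                study.registry.diametral_genes(arm=arm), stable_up
            ),
            "deg_t1": score_recovery(
                study.registry.feature_ids(layer="expression", arm=arm),
                deg_calls[t1].up | deg_calls[t1].down,
            ),
            "dmc_t1": score_recovery(
                study.registry.feature_ids(layer="methylation", arm=arm),
                dmc_calls[t1].up | dmc_calls[t1].down,
            ),
        }

        # Enrichment on the T1 expression layer.
        universe = list(de_tables[t1]["feature_id"])
        top_up, top_down = enr.select_top_n(de_tables[t1], deg_calls[t1], config.enrich_top_n)
        pathway_sets = enr.synthetic_pathway_collection(universe, derive_seed(base, 50))
        for direction, query in (("up", top_up), ("down", top_down)):
            if query:
                table = enr.enrich(query, pathway_sets, universe)
                save(
                    f"enrichment_{arm}_{direction}.tsv",
                    lambda p, t=table: t.to_csv(p, sep="\t", index=False),
                )
        overlap = enr.pathway_overlap_report(deg_calls[t1], pathway_sets)
        save(
            f"pathway_overlap_{arm}.tsv",
            lambda p, t=overlap: t.to_csv(p, sep="\t", index=False),
        )
        summary["arms"][arm] = arm_summary

    if filter_report is not None:
        save("filter_report.json", filter_report.to_json)
        summary["filtering"] = rep.summarize_filtering(filter_report)
    save("venn_counts.json", lambda p: Path(p).write_text(json.dumps(venn, indent=1, sort_keys=True)))

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    files.append("summary.json")
    (out / "run_manifest.json").write_text(
        json.dumps(
            {"config_hash": config.config_hash(), "seed": base, "files": sorted(files)},
            indent=1,
        )
    )
    marker.unlink()
    return summary
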