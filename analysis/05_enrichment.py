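"""Over-representation analysis of the top called genes.

Top-100 up/down DEGs at T1 are tested against a synthetic pathway
collection (set sizes mirror the curated lists the overlap report is
modeled on; membership is random, so enrichment p-values here only
exercise the machinery).  Also writes the curated-pathway overlap report.
"""

from pathlib import Path

from persistome import enrichment as enr
from persistome import io as pio
from persistome import stats
from persistome.config import AnalysisConfig
from persistome.pipeline import derive_seed

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "study"


def main() -> None:
    cfg = AnalysisConfig.from_yaml(STUDY / "config.yaml")
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)

    for arm in ("TGFB1", "IL6"):
        table = pio.read_diff_table(ROOT / "transcriptome" / f"de_{arm}_T1.tsv")
        calls = stats.call_features(table, cfg.p_max, cfg.min_fold)
        universe = list(table["feature_id"])
        collection = enr.synthetic_pathway_collection(universe, derive_seed(cfg.seed, 50))
        enr.write_gmt(collection, out / "synthetic_pathways.gmt")
        top_up, top_down = enr.select_top_n(table, calls, cfg.enrich_top_n)
        for direction, query in (("up", top_up), ("down", top_down)):
            if not query:
                print(f"{arm} {direction}: no called genes")
                continue
            result = enr.enrich(query, collection, universe)
            result.to_csv(out / f"enrichment_{arm}_{direction}.tsv", sep="\t", index=False)
            best = result.iloc[0]
            print(f"{arm} {direction}: query {best['query_size']} genes; best set "
                  f"{best['set_name']} (k={best['overlap']}/{best['set_size']}, "
                  f"p={best['p_value']:.3g}, q={best['q_value']:.3g})")
        overlap = enr.pathway_overlap_report(calls, collection)
        overlap.to_csv(out / f"pathway_overlap_{arm}.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
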