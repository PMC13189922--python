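"""Differential expression per arm and timepoint, plus PCA.

Low-count CPM filter, TMM normalization, log2-CPM with mean-variance
precision weights, the paired moderated contrast treated-vs-MOCK, and a
PCA of all samples on the top-variance genes.
"""

from pathlib import Path

from persistome import io as pio
from persistome import stats
from persistome import transcriptome as rna
from persistome.config import AnalysisConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "study"


def main() -> None:
    cfg = AnalysisConfig.from_yaml(STUDY / "config.yaml")
    sheet = pio.read_sample_sheet(STUDY / "sample_sheet.tsv")
    counts = pio.read_matrix(STUDY / "counts.tsv", "gene_id")
    out = ROOT / "transcriptome"
    out.mkdir(parents=True, exist_ok=True)

    for arm in ("TGFB1", "IL6"):
        for tp in ("T1", "T2"):
            table = rna.de_pipeline(counts, sheet, arm, tp)
            pio.write_diff_table(table, out / f"de_{arm}_{tp}.tsv")
            calls = stats.call_features(table, cfg.p_max, cfg.min_fold)
            print(f"{arm}@{tp}: {len(calls.up)} up + {len(calls.down)} down DEGs "
                  f"of {len(table)} tested")

    kept = rna.filter_low_expression(counts, sheet)
    factors = rna.tmm_normalize(kept)
    factors.to_frame().to_csv(out / "norm_factors.tsv", sep="\t", index=False)
    logcpm = rna.log_cpm(kept, factors)
    pca = rna.pca_top_features(logcpm, min(cfg.pca_top_n, logcpm.shape[0]))
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    frac = ", ".join(f"PC{i + 1} {100 * v:.1f}%" for i, v in enumerate(pca.variance_fraction[:3]))
    print(f"PCA on {len(pca.features)} genes: {frac}")


if __name__ == "__main__":
    main()
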