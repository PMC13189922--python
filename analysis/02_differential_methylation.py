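"""Differential methylation per arm and timepoint.

Probe QC (detection-p filter, optional blacklist/sex removal), quantile
normalization of beta values, logit2 transform, and the paired moderated
contrast treated-vs-MOCK at each timepoint.  Writes the DMC tables, the
filter report and the region/island distribution summaries.
"""

from pathlib import Path

import pandas as pd

from persistome import io as pio
from persistome import methylome as meth
from persistome import stats
from persistome.config import AnalysisConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "study"


def main() -> None:
    cfg = AnalysisConfig.from_yaml(STUDY / "config.yaml")
    sheet = pio.read_sample_sheet(STUDY / "sample_sheet.tsv")
    manifest = pio.read_manifest(STUDY / "probe_manifest.tsv")
    beta = pio.read_beta(STUDY / "beta.tsv", STUDY / "detection_p.tsv")
    out = ROOT / "methylome"
    out.mkdir(parents=True, exist_ok=True)

    for arm in ("TGFB1", "IL6"):
        for tp in ("T1", "T2"):
            table, report = meth.dm_pipeline(
                beta, sheet, arm, tp,
                manifest=manifest,
                detection_threshold=cfg.detection_threshold,
            )
            pio.write_diff_table(table, out / f"dm_{arm}_{tp}.tsv")
            calls = stats.call_features(table, cfg.p_max, cfg.min_fold)
            dist = meth.region_distribution(calls, manifest)
            pd.concat(
                [dist.regions.assign(kind="region"), dist.islands.assign(kind="island")]
            ).to_csv(out / f"dmc_distribution_{arm}_{tp}.tsv", sep="\t", index=False)
            print(f"{arm}@{tp}: {len(calls.up)} hyper + {len(calls.down)} hypo DMCs "
                  f"of {len(table)} tested")
        report.to_json(out / "filter_report.json")
    print(f"filtering: {report.initial} -> {report.remaining} probes "
          f"({', '.join(f'{n}: -{r}' for n, r, _ in report.stages)})")


if __name__ == "__main__":
    main()
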