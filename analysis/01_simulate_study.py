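"""Generate the synthetic two-timepoint cytokine-stimulation study.

Three keratinocyte lines x {MOCK, TGFB1, IL6} x {T1, T2}; a methylation
array layer and an RNA-seq count layer over a shared gene vocabulary, with
50 transient DMCs/DEGs per treated arm and three planted diametral-
persistent genes (two on TGFB1, one on IL6).  Writes the raw matrices and
the truth registry under results/study/.
"""

from pathlib import Path

from persistome import io as pio
from persistome.config import benchmark_config
from persistome.pipeline import simulate_study

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = benchmark_config(seed=seed)
    cfg.to_yaml(OUT / "config.yaml")
    study = simulate_study(cfg)
    pio.write_sample_sheet(study.sheet, OUT / "sample_sheet.tsv")
    pio.write_manifest(study.manifest, OUT / "probe_manifest.tsv")
    pio.write_matrix(study.beta.values, OUT / "beta.tsv")
    pio.write_matrix(study.beta.detection_p, OUT / "detection_p.tsv")
    pio.write_matrix(study.counts, OUT / "counts.tsv")
    study.registry.to_json(OUT / "truth_registry.json")
    diametral = sorted(study.registry.diametral_genes())
    print(f"samples: {len(study.sheet)}; probes: {study.beta.values.shape[0]}; "
          f"genes: {study.counts.shape[0]}")
    print(f"planted diametral-persistent genes: {diametral}")


if __name__ == "__main__":
    main()
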