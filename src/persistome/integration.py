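"""Methylome-transcriptome integration and persistence analysis.

The bespoke inference of the pipeline: called DMCs are restricted to
promoter region classes (TSS200, TSS1500, 5'UTR, 1st exon) and mapped to
genes; each gene present in both omics layers is classified by whether its
expression direction and promoter methylation direction are inverse
("diametral": up + hypomethylated, or down + hypermethylated); and the
classification is intersected across the two timepoints to yield the
headline output — genes that stay diametrally deregulated after the
stimulus is withdrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import AnnotationError
from .stats import FeatureCalls
from .synthetic import PROMOTER_REGIONS

__all__ = [
    "PromoterDmcMap",
    "PersistencePartition",
    "map_promoter_dmcs",
    "diametral_overlap",
    "persistence_partition",
    "stable_diametral_genes",
    "INTEGRATION_CLASSES",
]

INTEGRATION_CLASSES = ("diametral_up", "diametral_down", "non_diametral", "conflicting")


@dataclass
class PromoterDmcMap:
    """gene -> [(probe_id, direction, region_class), ...] for promoter DMCs."""

    genes: dict = field(default_factory=dict)
    n_assignments: int = 0

    def directions(self, gene: str) -> set:
        return {d for _, d, _ in self.genes.get(gene, [])}


def map_promoter_dmcs(dmc_calls: FeatureCalls, manifest: pd.DataFrame) -> PromoterDmcMap:
    """Restrict called DMCs to promoter annotations and group them by gene.

    Each called probe contributes one entry per (gene, promoter-region)
    annotation in the manifest; probes without any promoter annotation are
    dropped.  ``n_assignments`` counts the surviving DMC-gene assignments.
    """
    direction = {p: "hyper" for p in dmc_calls.up}
    direction.update({p: "hypo" for p in dmc_calls.down})
    known = set(manifest["probe_id"])
    missing = set(direction) - known
    if missing:
        raise AnnotationError(
            f"called probes absent from manifest: {sorted(missing)[:5]}"
        )
    promoter = manifest[
        manifest["probe_id"].isin(direction)
        & manifest["region_class"].isin(PROMOTER_REGIONS)
        & (manifest["gene"] != "")
    ]
    pmap = PromoterDmcMap()
    for row in promoter.itertuples(index=False):
        pmap.genes.setdefault(row.gene, []).append(
            (row.probe_id, direction[row.probe_id], row.region_class)
        )
        pmap.n_assignments += 1
    return pmap


def diametral_overlap(deg_calls: FeatureCalls, pmap: PromoterDmcMap) -> pd.DataFrame:
    """Classify genes present in both layers by direction pairing.

    up + >=1 hypo promoter DMC -> ``diametral_up``; down + >=1 hyper ->
    ``diametral_down``; both hyper and hypo promoter DMCs -> ``conflicting``
    (never counted diametral); any other pairing -> ``non_diametral``.
    Returns the integration table sorted by gene.
    """
    rows = []
    for gene in sorted(set(pmap.genes) & (deg_calls.up | deg_calls.down)):
        entries = pmap.genes[gene]
        n_hypo = sum(1 for _, d, _ in entries if d == "hypo")
        n_hyper = sum(1 for _, d, _ in entries if d == "hyper")
        deg_dir = "up" if gene in deg_calls.up else "down"
        if n_hypo > 0 and n_hyper > 0:
            cls = "conflicting"
        elif deg_dir == "up" and n_hypo > 0:
            cls = "diametral_up"
        elif deg_dir == "down" and n_hyper > 0:
            cls = "diametral_down"
        else:
            cls = "non_diametral"
        rows.append(
            {
                "gene": gene,
                "deg_direction": deg_dir,
                "n_hypo_promoter": n_hypo,
                "n_hyper_promoter": n_hyper,
                "class": cls,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "deg_direction", "n_hypo_promoter", "n_hyper_promoter", "class"]
    )


@dataclass(frozen=True)
class PersistencePartition:
    """Direction-aware comparison of calls across the two timepoints.

    ``stable_up``/``stable_down`` require the same direction at T1 and T2;
    ``flipped`` features reverse direction; ``transient`` features are called
    at T1 only.  The four sets are disjoint.
    """

    stable_up: frozenset
    stable_down: frozenset
    transient: frozenset
    flipped: frozenset
    timepoints: tuple = ("T1", "T2")


def persistence_partition(
    calls_t1: FeatureCalls, calls_t2: FeatureCalls, timepoints=("T1", "T2")
) -> PersistencePartition:
    """Partition T1 calls by their fate at T2."""
    stable_up = calls_t1.up & calls_t2.up
    stable_down = calls_t1.down & calls_t2.down
    flipped = (calls_t1.up & calls_t2.down) | (calls_t1.down & calls_t2.up)
    called_t1 = calls_t1.up | calls_t1.down
    called_t2 = calls_t2.up | calls_t2.down
    transient = called_t1 - called_t2
    return PersistencePartition(
        stable_up=frozenset(stable_up),
        stable_down=frozenset(stable_down),
        transient=frozenset(transient),
        flipped=frozenset(flipped),
        timepoints=tuple(timepoints),
    )


def _genes_in_class(table: pd.DataFrame, cls: str) -> frozenset:
    if table.empty:
        return frozenset()
    return frozenset(table.loc[table["class"] == cls, "gene"])


def stable_diametral_genes(
    integ_t1: pd.DataFrame, integ_t2: pd.DataFrame
) -> tuple[frozenset, frozenset]:
    """Genes diametrally classified (same direction) at BOTH timepoints.

    Returns (stable diametral-up, stable diametral-down) — the pipeline's
    headline output: persistently deregulated genes whose promoter
    methylation stays inversely shifted after stimulus withdrawal.
    """
    up = _genes_in_class(integ_t1, "diametral_up") & _genes_in_class(integ_t2, "diametral_up")
    down = _genes_in_class(integ_t1, "diametral_down") & _genes_in_class(
        integ_t2, "diametral_down"
    )
    return frozenset(up), frozenset(down)
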