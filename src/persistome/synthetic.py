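"""Seeded synthetic data for the paired cytokine-stimulation design.

Emulates the study layout: three patient-derived keratinocyte lines, each
cultured under a solvent control (MOCK) and under cytokine arms (TGFB1,
IL6), profiled at two timepoints — T1 after four weeks of stimulation and
T2 after a further four weeks without the stimulus.  Two omics layers are
generated against a shared gene vocabulary:

* a methylation array layer: per-probe beta values drawn from a bimodal
  Beta mixture, perturbed on the M (logit2) scale by cell-line random
  effects, Gaussian noise, and planted treatment effects;
* an RNA-seq count layer: negative-binomial counts with library-size
  variation, lognormal cell-line effects, and planted fold changes.

Planted effects are either transient (present at T1 only) or persistent
(present at both timepoints); "diametral" genes couple a persistent
expression up-regulation with persistent hypomethylation of at least one
promoter probe of the same gene — the structure the integration stage is
designed to recover.  Every planted effect is recorded in a machine-
readable :class:`TruthRegistry` so recovery can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import CapacityError, DesignError, TruthConfigError

__all__ = [
    "PROMOTER_REGIONS",
    "REGION_CLASSES",
    "ISLAND_RELATIONS",
    "TruthEntry",
    "TruthRegistry",
    "BetaMatrix",
    "MethylTruthConfig",
    "ExprTruthConfig",
    "DiametralTruthConfig",
    "generate_design",
    "generate_probe_manifest",
    "simulate_methylome",
    "simulate_transcriptome",
    "plant_diametral_genes",
    "promoter_genes",
]

PROMOTER_REGIONS = frozenset({"TSS200", "TSS1500", "5UTR", "1stExon"})
REGION_CLASSES = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR", "Intergenic")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Default drawing proportions for non-forced genic probes.
_REGION_PROPS = {
    "TSS200": 0.10,
    "TSS1500": 0.15,
    "5UTR": 0.15,
    "1stExon": 0.05,
    "Body": 0.40,
    "3UTR": 0.15,
}
_ISLAND_PROPS = {
    "Island": 0.30,
    "N_Shore": 0.10,
    "S_Shore": 0.10,
    "N_Shelf": 0.05,
    "S_Shelf": 0.05,
    "OpenSea": 0.40,
}


# ---------------------------------------------------------------------------
# truth registry


@dataclass(frozen=True)
class TruthEntry:
    """One planted effect: a methylation M-shift or an expression log2 fold."""

    feature_id: str
    layer: str  # "methylation" | "expression"
    arm: str
    effect: float
    persistent: bool
    diametral_gene: str | None = None

    def __post_init__(self):
        if self.layer not in ("methylation", "expression"):
            raise TruthConfigError(f"unknown truth layer {self.layer!r}")


@dataclass
class TruthRegistry:
    """Machine-readable record of all planted effects."""

    entries: list = field(default_factory=list)

    def add(self, entry: TruthEntry) -> None:
        self.entries.append(entry)

    def extend(self, other: "TruthRegistry") -> None:
        self.entries.extend(other.entries)

    def select(self, layer=None, arm=None, persistent=None, sign=None) -> list:
        out = []
        for e in self.entries:
            if layer is not None and e.layer != layer:
                continue
            if arm is not None and e.arm != arm:
                continue
            if persistent is not None and e.persistent != persistent:
                continue
            if sign is not None and math.copysign(1, e.effect) != sign:
                continue
            out.append(e)
        return out

    def feature_ids(self, **kw) -> frozenset:
        return frozenset(e.feature_id for e in self.select(**kw))

    def diametral_genes(self, arm=None) -> frozenset:
        return frozenset(
            e.diametral_gene
            for e in self.entries
            if e.diametral_gene is not None and (arm is None or e.arm == arm)
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(e) for e in self.entries], fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRegistry":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(entries=[TruthEntry(**rec) for rec in raw])


@dataclass
class BetaMatrix:
    """Probe x sample beta values with matching detection p-values."""

    values: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.detection_p.index) or not self.values.columns.equals(
            self.detection_p.columns
        ):
            raise DesignError("beta and detection-p matrices must share axes")


# ---------------------------------------------------------------------------
# design & manifest


def generate_design(n_lines: int, arms, timepoints, seed: int = 0) -> pd.DataFrame:
    """Fully crossed sample sheet: every (line, arm, timepoint) exactly once."""
    if n_lines < 2:
        raise DesignError(f"need at least 2 cell lines for a model fit, got {n_lines}")
    arms = list(arms)
    if "MOCK" not in arms:
        raise DesignError("design must include the MOCK control arm")
    timepoints = list(timepoints)
    rows = []
    for i in range(1, n_lines + 1):
        line = f"L{i}"
        for arm in arms:
            for tp in timepoints:
                rows.append(
                    {
                        "sample_id": f"{line}_{arm}_{tp}",
                        "cell_line": line,
                        "arm": arm,
                        "timepoint": tp,
                    }
                )
    return pd.DataFrame(rows)


def generate_probe_manifest(
    n_genes: int,
    probes_per_gene: int,
    frac_intergenic: float,
    seed: int,
    region_props: dict | None = None,
    island_props: dict | None = None,
) -> pd.DataFrame:
    """Array-style probe manifest: one row per probe-gene-region assignment.

    Each gene is guaranteed at least one promoter-class probe and one Body
    probe; remaining genic probes draw their region class from
    ``region_props``.  Intergenic probes (no gene symbol) are appended so
    they make up ``frac_intergenic`` of all probes.
    """
    if n_genes < 1:
        raise DesignError("n_genes must be >= 1")
    if probes_per_gene < 2:
        raise CapacityError("need >= 2 probes per gene to guarantee promoter + Body coverage")
    if not (0 <= frac_intergenic < 1):
        raise DesignError("frac_intergenic must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    region_props = dict(region_props or _REGION_PROPS)
    island_props = dict(island_props or _ISLAND_PROPS)
    reg_names = list(region_props)
    reg_p = np.array([region_props[r] for r in reg_names], dtype=float)
    reg_p /= reg_p.sum()
    isl_names = list(island_props)
    isl_p = np.array([island_props[r] for r in isl_names], dtype=float)
    isl_p /= isl_p.sum()
    promoter_choices = sorted(PROMOTER_REGIONS)

    n_genic = n_genes * probes_per_gene
    n_intergenic = round(n_genic * frac_intergenic / (1.0 - frac_intergenic))

    rows = []
    probe_no = 0
    pos = {}
    for g in range(1, n_genes + 1):
        gene = f"G{g:05d}"
        chrom = f"chr{(g - 1) % 22 + 1}"
        regions = [promoter_choices[int(rng.integers(len(promoter_choices)))], "Body"]
        extra = rng.choice(reg_names, size=probes_per_gene - 2, p=reg_p)
        regions.extend(extra.tolist())
        for region in regions:
            probe_no += 1
            pos[chrom] = pos.get(chrom, 0) + int(rng.integers(100, 5000))
            rows.append(
                {
                    "probe_id": f"cg{probe_no:07d}",
                    "chrom": chrom,
                    "pos": pos[chrom],
                    "gene": gene,
                    "region_class": region,
                    "island_relation": str(rng.choice(isl_names, p=isl_p)),
                }
            )
    for _ in range(n_intergenic):
        probe_no += 1
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos[chrom] = pos.get(chrom, 0) + int(rng.integers(100, 5000))
        rows.append(
            {
                "probe_id": f"cg{probe_no:07d}",
                "chrom": chrom,
                "pos": pos[chrom],
                "gene": "",
                "region_class": "Intergenic",
                "island_relation": str(rng.choice(isl_names, p=isl_p)),
            }
        )
    return pd.DataFrame(rows)


def promoter_genes(manifest: pd.DataFrame) -> list:
    """Genes with at least one promoter-class probe, in manifest order."""
    mask = manifest["region_class"].isin(PROMOTER_REGIONS) & (manifest["gene"] != "")
    return list(dict.fromkeys(manifest.loc[mask, "gene"]))


# ---------------------------------------------------------------------------
# truth configurations


@dataclass
class MethylTruthConfig:
    """Planted-DMC configuration, applied per treated arm.

    ``delta`` is the M-scale (logit2) shift; ``noise_sd`` the per-observation
    logit noise; ``line_sd`` the per-(probe, line) random effect.  A fraction
    of probes is planted to fail the detection-p filter in every sample.
    """

    n_hyper_transient: int = 0
    n_hypo_transient: int = 0
    n_hyper_persistent: int = 0
    n_hypo_persistent: int = 0
    delta: float = 2.0
    noise_sd: float = 0.3
    line_sd: float = 0.1
    frac_failing_detection: float = 0.0
    detection_threshold: float = 1e-10

    def total_planted(self) -> int:
        return (
            self.n_hyper_transient
            + self.n_hypo_transient
            + self.n_hyper_persistent
            + self.n_hypo_persistent
        )

    def validate(self) -> None:
        if self.total_planted() > 0 and self.delta == 0:
            raise TruthConfigError("planted DMCs requested but delta is 0 (degenerate truth)")
        if not (0 <= self.frac_failing_detection < 1):
            raise TruthConfigError("frac_failing_detection must lie in [0, 1)")


@dataclass
class ExprTruthConfig:
    """Planted-DEG configuration, applied per treated arm.

    ``fold`` is the linear fold change (>= 1); up effects multiply the mean
    by ``fold``, down effects by ``1/fold``.  ``dispersion`` is the NB
    dispersion (variance = mu + dispersion * mu^2); library sizes are drawn
    uniformly from ``libsize_range``.
    """

    n_up_transient: int = 0
    n_down_transient: int = 0
    n_up_persistent: int = 0
    n_down_persistent: int = 0
    fold: float = 2.0
    dispersion: float = 0.1
    baseline_log_mean: float = math.log(200.0)
    baseline_log_sd: float = 1.0
    libsize_range: tuple = (0.5, 2.0)
    line_sd: float = 0.1
    min_planted_baseline: float = 50.0

    def total_planted(self) -> int:
        return (
            self.n_up_transient
            + self.n_down_transient
            + self.n_up_persistent
            + self.n_down_persistent
        )

    def validate(self) -> None:
        if self.fold < 1:
            raise TruthConfigError("fold for an 'up' effect must be >= 1 (inconsistent truth)")
        if self.dispersion < 0:
            raise TruthConfigError("dispersion must be >= 0")


@dataclass
class DiametralTruthConfig:
    """Configuration for planted diametral-persistent genes."""

    fold: float = 2.0
    delta: float = 2.0
    arm: str = "TGFB1"
    n_promoter_probes: int = 1

    def validate(self) -> None:
        if self.fold < 1:
            raise TruthConfigError("diametral fold must be >= 1")
        if self.delta <= 0:
            raise TruthConfigError("diametral delta must be > 0 (applied as hypomethylation)")
        if self.n_promoter_probes < 1:
            raise TruthConfigError("need at least one promoter probe per diametral gene")


# ---------------------------------------------------------------------------
# simulators


def _treated_arms(sheet: pd.DataFrame) -> list:
    return [a for a in dict.fromkeys(sheet["arm"]) if a != "MOCK"]


def _effect_applies(entry: TruthEntry, arm: str, timepoint: str, t1: str) -> bool:
    if arm != entry.arm:
        return False
    return timepoint == t1 or entry.persistent


def simulate_methylome(
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    truth_cfg: MethylTruthConfig,
    seed: int,
    extra_truth: TruthRegistry | None = None,
    avoid_probes=frozenset(),
) -> tuple[BetaMatrix, TruthRegistry]:
    """Generate beta values + detection p-values with planted DMCs.

    Baseline beta per probe comes from the bimodal mixture
    0.45*Beta(2,10) + 0.45*Beta(10,2) + 0.1*Beta(5,5); everything else acts
    additively on the M scale before back-transforming.  Effects listed in
    ``extra_truth`` (e.g. diametral promoter hypomethylation) are applied on
    top of the per-arm planted counts and merged into the returned registry.
    Probes in ``avoid_probes`` never receive a planted effect — the study
    driver passes the promoter probes of genes already carrying expression
    effects, so no accidental (untagged) diametral pair is planted.
    """
    truth_cfg.validate()
    rng = np.random.default_rng(seed)
    probes = list(dict.fromkeys(manifest["probe_id"]))
    n_probes = len(probes)
    probe_index = {p: i for i, p in enumerate(probes)}
    samples = sheet["sample_id"].tolist()
    lines = list(dict.fromkeys(sheet["cell_line"]))
    timepoints = list(dict.fromkeys(sheet["timepoint"]))
    t1 = timepoints[0]

    # Baseline beta: bimodal mixture, then to M scale.
    comp = rng.choice(3, size=n_probes, p=[0.45, 0.45, 0.1])
    baseline = np.where(
        comp == 0,
        rng.beta(2, 10, size=n_probes),
        np.where(comp == 1, rng.beta(10, 2, size=n_probes), rng.beta(5, 5, size=n_probes)),
    )
    m0 = np.log2(baseline / (1.0 - baseline))
    line_eff = rng.normal(0.0, truth_cfg.line_sd, size=(n_probes, len(lines)))

    registry = TruthRegistry()
    if extra_truth is not None:
        for e in extra_truth.select(layer="methylation"):
            if e.feature_id not in probe_index:
                raise TruthConfigError(f"extra truth probe {e.feature_id!r} not in manifest")
            registry.add(e)
    reserved = registry.feature_ids(layer="methylation") | frozenset(avoid_probes)

    free = [p for p in probes if p not in reserved]
    plan = [
        ("hyper", False, truth_cfg.n_hyper_transient),
        ("hypo", False, truth_cfg.n_hypo_transient),
        ("hyper", True, truth_cfg.n_hyper_persistent),
        ("hypo", True, truth_cfg.n_hypo_persistent),
    ]
    for arm in _treated_arms(sheet):
        need = truth_cfg.total_planted()
        if need > len(free):
            raise CapacityError(f"cannot plant {need} DMCs for {arm}: only {len(free)} free probes")
        chosen = rng.choice(len(free), size=need, replace=False) if need else np.array([], int)
        picked = [free[i] for i in chosen]
        free = [p for j, p in enumerate(free) if j not in set(chosen.tolist())]
        it = iter(picked)
        for direction, persistent, count in plan:
            sgn = 1.0 if direction == "hyper" else -1.0
            for _ in range(count):
                registry.add(
                    TruthEntry(
                        feature_id=next(it),
                        layer="methylation",
                        arm=arm,
                        effect=sgn * truth_cfg.delta,
                        persistent=persistent,
                    )
                )

    # Effect lookup: probe -> list of entries.
    effects: dict[str, list] = {}
    for e in registry.select(layer="methylation"):
        effects.setdefault(e.feature_id, []).append(e)

    M = np.empty((n_probes, len(samples)))
    for j, row in enumerate(sheet.itertuples(index=False)):
        col = m0 + line_eff[:, lines.index(row.cell_line)]
        if truth_cfg.noise_sd > 0:
            col = col + rng.normal(0.0, truth_cfg.noise_sd, size=n_probes)
        for probe, entries in effects.items():
            for e in entries:
                if _effect_applies(e, row.arm, row.timepoint, t1):
                    col[probe_index[probe]] += e.effect
        M[:, j] = col

    beta = 1.0 / (1.0 + 2.0 ** (-M))

    # Detection p-values: planted failing probes fail in every sample; the
    # failing set avoids effect-carrying probes so planted truth survives QC.
    thr = truth_cfg.detection_threshold
    detp = rng.uniform(0.0, thr, size=(n_probes, len(samples)))
    n_fail = round(truth_cfg.frac_failing_detection * n_probes)
    if n_fail:
        eligible = [p for p in probes if p not in effects]
        if n_fail > len(eligible):
            raise CapacityError("failing-detection fraction exceeds unplanted probe count")
        fail_idx = rng.choice(len(eligible), size=n_fail, replace=False)
        for i in fail_idx:
            detp[probe_index[eligible[i]], :] = rng.uniform(thr, 1.0, size=len(samples))

    values = pd.DataFrame(beta, index=pd.Index(probes, name="probe_id"), columns=samples)
    detection = pd.DataFrame(detp, index=values.index.copy(), columns=samples)
    return BetaMatrix(values=values, detection_p=detection), registry


def simulate_transcriptome(
    genes,
    sheet: pd.DataFrame,
    truth_cfg: ExprTruthConfig,
    seed: int,
    extra_truth: TruthRegistry | None = None,
) -> tuple[pd.DataFrame, TruthRegistry]:
    """Generate an NB count matrix (genes x samples) with planted DEGs.

    Counts ~ NB(mu * line_factor * libsize * 2^effect, dispersion); at
    dispersion 0 the Poisson limit is used.  Planted effects go to genes with
    baseline mean >= ``min_planted_baseline`` so the truth is identifiable.
    """
    truth_cfg.validate()
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    samples = sheet["sample_id"].tolist()
    lines = list(dict.fromkeys(sheet["cell_line"]))
    timepoints = list(dict.fromkeys(sheet["timepoint"]))
    t1 = timepoints[0]

    mu = rng.lognormal(truth_cfg.baseline_log_mean, truth_cfg.baseline_log_sd, size=n_genes)
    line_fac = np.exp(rng.normal(0.0, truth_cfg.line_sd, size=(n_genes, len(lines))))
    lo, hi = truth_cfg.libsize_range
    libsize = rng.uniform(lo, hi, size=len(samples))

    registry = TruthRegistry()
    if extra_truth is not None:
        for e in extra_truth.select(layer="expression"):
            if e.feature_id not in gene_index:
                raise TruthConfigError(f"extra truth gene {e.feature_id!r} not in gene list")
            registry.add(e)
    reserved = registry.feature_ids(layer="expression")

    eligible = [g for g in genes if g not in reserved and mu[gene_index[g]] >= truth_cfg.min_planted_baseline]
    lfc = math.log2(truth_cfg.fold)
    plan = [
        ("up", False, truth_cfg.n_up_transient),
        ("down", False, truth_cfg.n_down_transient),
        ("up", True, truth_cfg.n_up_persistent),
        ("down", True, truth_cfg.n_down_persistent),
    ]
    for arm in _treated_arms(sheet):
        need = truth_cfg.total_planted()
        if need > len(eligible):
            raise CapacityError(
                f"cannot plant {need} DEGs for {arm}: only {len(eligible)} eligible genes"
            )
        chosen = rng.choice(len(eligible), size=need, replace=False) if need else np.array([], int)
        picked = [eligible[i] for i in chosen]
        eligible = [g for j, g in enumerate(eligible) if j not in set(chosen.tolist())]
        it = iter(picked)
        for direction, persistent, count in plan:
            sgn = 1.0 if direction == "up" else -1.0
            for _ in range(count):
                registry.add(
                    TruthEntry(
                        feature_id=next(it),
                        layer="expression",
                        arm=arm,
                        effect=sgn * lfc,
                        persistent=persistent,
                    )
                )

    effects: dict[str, list] = {}
    for e in registry.select(layer="expression"):
        effects.setdefault(e.feature_id, []).append(e)

    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    alpha = truth_cfg.dispersion
    for j, row in enumerate(sheet.itertuples(index=False)):
        mean = mu * line_fac[:, lines.index(row.cell_line)] * libsize[j]
        for gene, entries in effects.items():
            for e in entries:
                if _effect_applies(e, row.arm, row.timepoint, t1):
                    mean[gene_index[gene]] *= 2.0**e.effect
        if alpha < 1e-12:
            counts[:, j] = rng.poisson(mean)
        else:
            size = 1.0 / alpha
            counts[:, j] = rng.negative_binomial(size, size / (size + mean))

    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    return matrix, registry


def plant_diametral_genes(
    n_genes: int,
    manifest: pd.DataFrame,
    truth_cfg: DiametralTruthConfig,
    seed: int,
) -> TruthRegistry:
    """Plan persistent diametral genes: up-regulated + promoter-hypomethylated.

    Returns a registry fragment (one expression entry with positive log2
    fold, plus >= 1 promoter-probe methylation entry with negative M-shift,
    all persistent and tagged with the gene) to be passed as ``extra_truth``
    to both simulators.
    """
    truth_cfg.validate()
    candidates = promoter_genes(manifest)
    if n_genes > len(candidates):
        raise CapacityError(
            f"requested {n_genes} diametral genes but only {len(candidates)} "
            "genes carry promoter probes"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_genes, replace=False) if n_genes else []
    registry = TruthRegistry()
    promoter_rows = manifest[
        manifest["region_class"].isin(PROMOTER_REGIONS) & (manifest["gene"] != "")
    ]
    for i in idx:
        gene = candidates[i]
        registry.add(
            TruthEntry(
                feature_id=gene,
                layer="expression",
                arm=truth_cfg.arm,
                effect=math.log2(truth_cfg.fold),
                persistent=True,
                diametral_gene=gene,
            )
        )
        probes = list(dict.fromkeys(promoter_rows.loc[promoter_rows["gene"] == gene, "probe_id"]))
        take = min(truth_cfg.n_promoter_probes, len(probes))
        for probe in probes[:take]:
            registry.add(
                TruthEntry(
                    feature_id=probe,
                    layer="methylation",
                    arm=truth_cfg.arm,
                    effect=-truth_cfg.delta,
                    persistent=True,
                    diametral_gene=gene,
                )
            )
    return registry
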