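"""Methylation-array analysis stage.

Probe-level QC filtering with sequential bookkeeping, between-array
quantile normalization of beta values, the beta -> M logit2 transform, a
per-arm/per-timepoint differential-methylation contrast via the moderated
linear model, and distribution summaries of the resulting DMCs across
genomic region classes and CpG-island relations.

The differential contrast at each timepoint compares treated samples with
their parallel-cultured MOCK controls at the same timepoint, pairing by
cell line (design: intercept + cell-line indicators + treatment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .errors import AnnotationError, DesignError, FilterError
from .rounding import percent
from .synthetic import BetaMatrix

__all__ = [
    "FilterReport",
    "DistributionSummary",
    "SEX_CHROMS",
    "filter_probes",
    "beta_to_m",
    "m_to_beta",
    "treatment_design",
    "dm_pipeline",
    "region_distribution",
]

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class FilterReport:
    """Sequential filter bookkeeping: stages are applied in order, so the
    per-stage removal counts are disjoint by construction."""

    initial: int
    stages: list = field(default_factory=list)  # (name, n_removed, n_remaining)

    def record(self, name: str, n_removed: int) -> None:
        remaining = self.remaining - n_removed
        if remaining < 0:
            raise FilterError(f"stage {name!r} removes more probes than remain")
        self.stages.append((name, int(n_removed), int(remaining)))

    @property
    def remaining(self) -> int:
        return self.stages[-1][2] if self.stages else self.initial

    def validate(self) -> None:
        prev = self.initial
        for name, removed, remaining in self.stages:
            if remaining != prev - removed or removed < 0:
                raise FilterError(f"inconsistent filter stage {name!r}")
            prev = remaining

    def to_json(self, path) -> None:
        payload = {
            "initial": self.initial,
            "stages": [
                {"stage": n, "n_removed": r, "n_remaining": m} for n, r, m in self.stages
            ],
            "final_remaining": self.remaining,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def filter_probes(
    beta: BetaMatrix,
    blacklist,
    manifest: pd.DataFrame | None,
    detection_threshold: float,
    drop_sex_chroms: bool = True,
    detection_rule: str = "any",
) -> tuple[BetaMatrix, FilterReport]:
    """Two-stage probe QC.

    Stage 1 drops probes failing the detection-p threshold (``"any"``: p >=
    threshold in at least one sample; ``"mean"``: mean p >= threshold).
    Stage 2 drops remaining probes that are blacklisted (SNP-associated /
    cross-hybridizing, supplied by the user) or on a sex chromosome.
    """
    if not (0 < detection_threshold < 1):
        raise FilterError("detection_threshold must lie in (0, 1)")
    blacklist = frozenset(blacklist)
    values, detp = beta.values, beta.detection_p

    if detection_rule == "any":
        failing = (detp.to_numpy() >= detection_threshold).any(axis=1)
    elif detection_rule == "mean":
        failing = detp.to_numpy().mean(axis=1) >= detection_threshold
    else:
        raise FilterError(f"unknown detection rule {detection_rule!r}")
    report = FilterReport(initial=values.shape[0])
    keep1 = values.index[~failing]
    report.record("detection", int(failing.sum()))

    drop2 = pd.Series(False, index=keep1)
    drop2 |= keep1.isin(blacklist)
    if drop_sex_chroms:
        if manifest is None:
            raise FilterError("sex-chromosome filtering requires a manifest")
        sex_probes = set(manifest.loc[manifest["chrom"].isin(SEX_CHROMS), "probe_id"])
        drop2 |= keep1.isin(sex_probes)
    keep2 = keep1[~drop2.to_numpy()]
    report.record("blacklist_sex", int(drop2.sum()))

    if len(keep2) == 0:
        raise FilterError("all probes removed by filtering")
    report.validate()
    filtered = BetaMatrix(values=values.loc[keep2], detection_p=detp.loc[keep2])
    return filtered, report


def beta_to_m(beta, epsilon: float = 1e-6):
    """M = log2(beta / (1 - beta)) with beta clamped to [epsilon, 1-epsilon]."""
    if not (0 < epsilon < 0.5):
        raise FilterError("epsilon must lie in (0, 0.5)")
    arr = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit2 transform."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + 2.0**(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if np.isscalar(m):
        return float(b)
    return b


def treatment_design(sheet: pd.DataFrame, arm: str, timepoint: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subset the sheet to MOCK + ``arm`` at ``timepoint`` and build the
    paired design matrix (intercept, cell-line indicators, treatment).

    Returns (sub_sheet, design); the treatment column is last.
    """
    sub = sheet[(sheet["timepoint"] == timepoint) & (sheet["arm"].isin(["MOCK", arm]))]
    lines_with_both = [
        line
        for line, grp in sub.groupby("cell_line", sort=False)
        if {"MOCK", arm} <= set(grp["arm"])
    ]
    if len(lines_with_both) < 2:
        raise DesignError(
            f"need MOCK and {arm} at {timepoint} for >= 2 cell lines; "
            f"found {len(lines_with_both)}"
        )
    sub = sub[sub["cell_line"].isin(lines_with_both)].reset_index(drop=True)
    lines = list(dict.fromkeys(sub["cell_line"]))
    cols = {"intercept": np.ones(len(sub))}
    for line in lines[1:]:
        cols[f"line_{line}"] = (sub["cell_line"] == line).astype(float).to_numpy()
    cols["treatment"] = (sub["arm"] == arm).astype(float).to_numpy()
    design = pd.DataFrame(cols, index=sub["sample_id"])
    return sub, design


def dm_pipeline(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    arm: str,
    timepoint: str,
    manifest: pd.DataFrame | None = None,
    blacklist=frozenset(),
    detection_threshold: float = 1e-10,
    drop_sex_chroms: bool = False,
    detection_rule: str = "any",
    normalize_scale: str = "beta",
    epsilon: float = 1e-6,
    quantile_norm: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full differential-methylation contrast for one arm at one timepoint.

    filter -> quantile normalize -> logit2 -> moderated linear model on the
    treatment coefficient.  ``normalize_scale`` selects whether quantile
    normalization acts on beta (default) or on M values.  logFC is the
    M-scale treatment contrast: positive = hypermethylated.
    """
    filtered, report = filter_probes(
        beta, blacklist, manifest, detection_threshold, drop_sex_chroms, detection_rule
    )
    sub, design = treatment_design(sheet, arm, timepoint)
    values = filtered.values[sub["sample_id"].tolist()]
    if not quantile_norm:
        M = beta_to_m(values, epsilon)
    elif normalize_scale == "beta":
        M = beta_to_m(stats.quantile_normalize(values), epsilon)
    elif normalize_scale == "m":
        M = stats.quantile_normalize(beta_to_m(values, epsilon))
    else:
        raise FilterError(f"unknown normalize_scale {normalize_scale!r}")
    fit = stats.fit_feature_lm(M, design)
    result = stats.ebayes_moderate(fit, contrast=design.shape[1] - 1)
    table = stats.make_diff_table(result, feature_ids=M.index.to_numpy())
    return table, report


@dataclass
class DistributionSummary:
    """Per-category DMC counts and percents, split hyper/hypo.

    ``regions`` counts probe-annotation assignments (a probe annotated to
    several region classes contributes once per assignment); ``islands``
    counts called probes once each.  Percents are of the respective totals,
    half-up at one decimal.
    """

    regions: pd.DataFrame
    islands: pd.DataFrame


def _category_table(assign: pd.DataFrame, categories) -> pd.DataFrame:
    total = len(assign)
    rows = []
    for cat in categories:
        grp = assign[assign["category"] == cat]
        n_hyper = int((grp["direction"] == "hyper").sum())
        n_hypo = int((grp["direction"] == "hypo").sum())
        n = n_hyper + n_hypo
        rows.append(
            {
                "category": cat,
                "n_hyper": n_hyper,
                "n_hypo": n_hypo,
                "n_total": n,
                "percent": percent(n, total, 1) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def region_distribution(calls: stats.FeatureCalls, manifest: pd.DataFrame) -> DistributionSummary:
    """Distribution of DMCs across region classes and island relations."""
    called = {p: "hyper" for p in calls.up}
    called.update({p: "hypo" for p in calls.down})
    known = set(manifest["probe_id"])
    missing = set(called) - known
    if missing:
        raise AnnotationError(f"called probes missing from manifest: {sorted(missing)[:5]}")

    ann = manifest[manifest["probe_id"].isin(called)]
    region_assign = pd.DataFrame(
        {
            "category": ann["region_class"].to_numpy(),
            "direction": [called[p] for p in ann["probe_id"]],
        }
    )
    island_ann = ann.drop_duplicates("probe_id")
    island_assign = pd.DataFrame(
        {
            "category": island_ann["island_relation"].to_numpy(),
            "direction": [called[p] for p in island_ann["probe_id"]],
        }
    )
    region_cats = list(dict.fromkeys(manifest["region_class"]))
    island_cats = list(dict.fromkeys(manifest["island_relation"]))
    return DistributionSummary(
        regions=_category_table(region_assign, region_cats),
        islands=_category_table(island_assign, island_cats),
    )
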