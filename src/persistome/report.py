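"""Printed-summary arithmetic, qPCR validation math, and tissue comparison.

These are the bookkeeping operations behind the numbers a study report
prints: filter accounting, call-count percentages at the precision each
figure uses, ddCq relative expression from Cq tables, and a per-gene
rank-sum comparison of two tissue groups on a user-supplied normalized
expression table.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats as sps

from .errors import DesignError, FilterError, ParseError
from .methylome import FilterReport
from .rounding import percent
from .stats import FeatureCalls, bh_adjust, ranksum_exact

__all__ = [
    "summarize_filtering",
    "summarize_call_counts",
    "summarize_calls",
    "ddcq",
    "compare_tissue_groups",
    "CQ_COLUMNS",
]

CQ_COLUMNS = ["group", "gene", "is_reference", "replicate", "cq"]


def summarize_filtering(report: FilterReport) -> dict:
    """Echo the sequential filter accounting; raises on inconsistency."""
    report.validate()
    return {
        "initial": int(report.initial),
        "stages": [
            {"stage": name, "n_removed": removed, "n_remaining": remaining}
            for name, removed, remaining in report.stages
        ],
        "retained": int(report.remaining),
    }


def summarize_call_counts(
    n_up: int,
    n_down: int,
    n_tested: int,
    tested_ndigits: int = 1,
    direction_ndigits: int = 1,
) -> dict:
    """Call-count summary at the stated printing precision (half-up).

    ``percent_up``/``percent_down`` are of the total calls (hyper/hypo for
    methylation); ``percent_of_tested`` is of all tested features.
    """
    total = n_up + n_down
    if n_tested < total:
        raise FilterError("n_tested cannot be smaller than the number of calls")
    out = {"n_up": int(n_up), "n_down": int(n_down), "total": int(total)}
    if total == 0:
        out.update(percent_of_tested=None, percent_up=None, percent_down=None)
        return out
    out["percent_of_tested"] = percent(total, n_tested, tested_ndigits)
    out["percent_up"] = percent(n_up, total, direction_ndigits)
    out["percent_down"] = percent(n_down, total, direction_ndigits)
    return out


def summarize_calls(
    calls: FeatureCalls,
    n_tested: int,
    tested_ndigits: int = 1,
    direction_ndigits: int = 1,
) -> dict:
    return summarize_call_counts(
        len(calls.up), len(calls.down), n_tested, tested_ndigits, direction_ndigits
    )


def ddcq(cq: pd.DataFrame) -> pd.DataFrame:
    """Relative expression by the ddCq method.

    Expects a long table with columns group ('treated'/'control'), gene,
    is_reference, replicate, cq.  Per group, dCq = mean Cq(target) - mean
    Cq(reference); ddCq = dCq(treated) - dCq(control); fold = 2^(-ddCq).
    Replicate-level dCq values feed a paired t-test across replicates
    (pairing by replicate id), reported per gene when >= 2 pairs exist.
    """
    missing = [c for c in CQ_COLUMNS if c not in cq.columns]
    if missing:
        raise ParseError(f"Cq table lacks columns {missing}")
    if (cq["cq"] <= 0).any():
        raise ParseError("Cq values must be positive")
    ref = cq[cq["is_reference"]]
    targets = cq[~cq["is_reference"]]
    for group in ("treated", "control"):
        if (ref["group"] == group).sum() == 0:
            raise DesignError(f"reference gene measurements missing for group {group!r}")

    # Replicate-level reference means per group.
    ref_mean = ref.groupby(["group", "replicate"])["cq"].mean()
    ref_group_mean = ref.groupby("group")["cq"].mean()

    rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        group_stats = {}
        rep_dcq = {}
        for group in ("treated", "control"):
            gsub = sub[sub["group"] == group]
            if len(gsub) == 0:
                raise DesignError(f"gene {gene!r} lacks measurements for group {group!r}")
            group_stats[group] = gsub["cq"].mean() - ref_group_mean[group]
            per_rep = gsub.groupby("replicate")["cq"].mean()
            rep_dcq[group] = {
                rep: per_rep[rep] - ref_mean[(group, rep)]
                for rep in per_rep.index
                if (group, rep) in ref_mean.index
            }
        ddcq_value = group_stats["treated"] - group_stats["control"]
        paired = [
            (rep_dcq["treated"][r], rep_dcq["control"][r])
            for r in sorted(set(rep_dcq["treated"]) & set(rep_dcq["control"]))
        ]
        if len(paired) >= 2:
            t_vals = [a for a, _ in paired]
            c_vals = [b for _, b in paired]
            p_paired = float(sps.ttest_rel(t_vals, c_vals).pvalue)
        else:
            p_paired = float("nan")
        rows.append(
            {
                "gene": gene,
                "dcq_treated": group_stats["treated"],
                "dcq_control": group_stats["control"],
                "ddcq": ddcq_value,
                "fold_change": 2.0 ** (-ddcq_value),
                "n_pairs": len(paired),
                "p_paired_t": p_paired,
            }
        )
    return pd.DataFrame(rows)


def compare_tissue_groups(expr: pd.DataFrame, groups, labels: tuple) -> pd.DataFrame:
    """Per-gene rank-sum comparison of two sample groups.

    ``expr`` is genes x samples (a user-supplied normalized table);
    ``groups`` maps sample id -> label; ``labels`` names the two groups to
    compare.  Returns per gene: U, p (exact when feasible), group medians,
    and a BH-adjusted column across genes.
    """
    groups = dict(groups)
    label_a, label_b = labels
    known = set(groups.values())
    for lab in labels:
        if lab not in known:
            raise DesignError(f"unknown group label {lab!r}")
    cols_a = [s for s in expr.columns if groups.get(s) == label_a]
    cols_b = [s for s in expr.columns if groups.get(s) == label_b]
    if not cols_a or not cols_b:
        raise DesignError("each group needs at least one sample present in the table")

    rows = []
    for gene, values in expr.iterrows():
        x = values[cols_a].to_numpy(dtype=float)
        y = values[cols_b].to_numpy(dtype=float)
        u, p, method = ranksum_exact(x, y)
        rows.append(
            {
                "gene": gene,
                "U": u,
                "p_value": p,
                "method": method,
                f"median_{label_a}": float(pd.Series(x).median()),
                f"median_{label_b}": float(pd.Series(y).median()),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
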