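import numpy as np
import pandas as pd
import pytest

from persistome import synthetic as syn
from persistome.config import benchmark_config
from persistome.pipeline import simulate_study


@pytest.fixture
def sheet():
    """3 lines x {MOCK, TGFB1} x {T1, T2} paired design."""
    return syn.generate_design(3, ["MOCK", "TGFB1"], ["T1", "T2"], seed=0)


@pytest.fixture
def manifest():
    return syn.generate_probe_manifest(40, 5, 0.1, seed=3)


@pytest.fixture(scope="session")
def benchmark_study():
    """One seeded planted-truth study at validation-benchmark settings,
    scaled down for unit-test speed (same structure, fewer genes)."""
    cfg = benchmark_config(seed=11)
    cfg.simulation.n_genes = 400
    return cfg, simulate_study(cfg)


def permute_arms_within_lines(sheet, seed, treated="TGFB1"):
    """Paired-design null permutation: per line (and timepoint), swap the
    MOCK/treated labels with probability 1/2, keeping the design valid."""
    rng = np.random.default_rng(seed)
    out = sheet.copy()
    for (line, tp), idx in out.groupby(["cell_line", "timepoint"]).groups.items():
        sub = out.loc[idx]
        pair = sub[sub["arm"].isin(["MOCK", treated])]
        if len(pair) == 2 and rng.random() < 0.5:
            out.loc[pair.index, "arm"] = pair["arm"].to_numpy()[::-1]
    return out


def toy_diff_table(p_values, logfcs, ids=None):
    n = len(p_values)
    ids = ids if ids is not None else [f"f{i}" for i in range(n)]
    p = np.asarray(p_values, dtype=float)
    lfc = np.asarray(logfcs, dtype=float)
    return pd.DataFrame(
        {
            "feature_id": ids,
            "logFC": lfc,
            "t": np.sign(lfc) * 5.0,
            "p_value": p,
            "q_value": p,
            "mean_level": np.zeros(n),
        }
    )
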