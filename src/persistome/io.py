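"""Plain-text readers/writers for the pipeline's tabular interfaces.

Everything is TSV (pandas) or JSON; column names are part of the contract
between stages, so writers always emit the canonical order.
"""

from __future__ import annotations

import pandas as pd

from .errors import ParseError
from .stats import DIFF_TABLE_COLUMNS
from .synthetic import BetaMatrix

SHEET_COLUMNS = ["sample_id", "cell_line", "arm", "timepoint"]
MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "gene", "region_class", "island_relation"]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ParseError(f"sample sheet {path} lacks columns {missing}")
    if sheet["sample_id"].duplicated().any():
        raise ParseError(f"sample sheet {path} has duplicate sample_ids")
    return sheet[SHEET_COLUMNS]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "gene": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing:
        raise ParseError(f"manifest {path} lacks columns {missing}")
    man["gene"] = man["gene"].fillna("")
    return man[MANIFEST_COLUMNS]


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True)


def read_matrix(path, index_name: str) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index.name = index_name
    return mat


def write_beta(beta: BetaMatrix, values_path, detection_path) -> None:
    write_matrix(beta.values, values_path)
    write_matrix(beta.detection_p, detection_path)


def read_beta(values_path, detection_path) -> BetaMatrix:
    return BetaMatrix(
        values=read_matrix(values_path, "probe_id"),
        detection_p=read_matrix(detection_path, "probe_id"),
    )


def write_diff_table(table: pd.DataFrame, path) -> None:
    table[DIFF_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_diff_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    missing = [c for c in DIFF_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"differential table {path} lacks columns {missing}")
    return table[DIFF_TABLE_COLUMNS]


def read_blacklist(path) -> frozenset:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(genes):
            fh.write(f"{gene}\n")
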