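"""Tab-separated I/O for methylation bundles.

All on-disk artifacts are plain TSV (probes as rows, samples as columns for
matrices) so they can be inspected with standard command-line tools and round
trip losslessly through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

SAMPLE_SHEET_COLUMNS = ["sample", "subject", "tissue", "day_offset"]
ANNOTATION_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "genes",
    "genic_class",
    "tfbs",
    "enhancer",
    "open_chromatin",
    "mqtl",
    "snp_within_5bp",
    "context_specific",
]

FLAG_COLUMNS = ["tfbs", "enhancer", "open_chromatin", "mqtl", "snp_within_5bp", "context_specific"]


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples beta matrix (first column = probe ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_beta_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str, "subject": str, "tissue": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing required columns: {missing}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "genes": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing required columns: {missing}")
    for col in FLAG_COLUMNS:
        ann[col] = ann[col].astype(bool)
    ann["genes"] = ann["genes"].fillna("")
    return ann.set_index("probe_id", drop=False)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
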