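"""TSV readers/writers for every artifact the pipeline exchanges.

Schemas
-------
probe table      probe_set_id, probe_position, <one column per array_id>
array metadata   array_id, tissue, protocol, replicate
expression       probe_set_id, <one column per array_id>  (log2 values)
truth            probe_set_id, class (over|under), log2_shift
bias table       probe_set_id, <one column per array_id>
gene list        one probe_set_id per line

Write-then-read round-trips values at full precision (repr-level float
formatting).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datatypes import (
    ARRAY_META_COLUMNS,
    ExpressionMatrix,
    ProbeLevelDataset,
    SimConfig,
    SimTruth,
)

__all__ = [
    "write_probe_table", "read_probe_table",
    "write_array_metadata", "read_array_metadata",
    "write_expression", "read_expression",
    "write_truth", "read_truth",
    "write_gene_list", "read_gene_list",
    "write_sim_config", "read_sim_config",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input table (bad header, ragged rows, missing cells)."""


def write_probe_table(data: ProbeLevelDataset, path) -> None:
    out = data.intensities.reset_index()
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_probe_table(path, metadata_path) -> ProbeLevelDataset:
    try:
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("probe_set_id", "probe_position"):
        if col not in table.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    arrays = read_array_metadata(metadata_path)
    array_cols = [c for c in table.columns if c not in ("probe_set_id", "probe_position")]
    missing_meta = [c for c in array_cols if c not in arrays.index]
    if missing_meta:
        raise ParseError(
            f"{metadata_path}: no metadata for array columns {missing_meta}"
        )
    table = table.set_index(["probe_set_id", "probe_position"])
    if table.isna().any().any():
        cell = table.stack(dropna=False)
        bad = cell.index[cell.isna()][0]
        raise ParseError(f"{path}: missing intensity for cell {bad}")
    counts = table.groupby(level=0).size()
    if counts.nunique() != 1:
        bad = counts[counts != counts.mode().iloc[0]].index[:5]
        raise ParseError(f"{path}: probe sets with missing positions: {list(bad)}")
    data = ProbeLevelDataset(intensities=table[list(arrays.index)], arrays=arrays)
    data.validate()
    return data


def write_array_metadata(arrays: pd.DataFrame, path) -> None:
    arrays.rename_axis("array_id").reset_index().to_csv(path, sep="\t", index=False)


def read_array_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    expected = ("array_id",) + ARRAY_META_COLUMNS
    missing = [c for c in expected if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing columns {missing}")
    return meta.set_index("array_id")


def write_expression(expr: ExpressionMatrix, path, metadata_path=None) -> None:
    expr.values.rename_axis("probe_set_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    if metadata_path is not None:
        write_array_metadata(expr.arrays, metadata_path)


def read_expression(path, metadata_path) -> ExpressionMatrix:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "probe_set_id" not in table.columns:
        raise ParseError(f"{path}: missing required column 'probe_set_id'")
    arrays = read_array_metadata(metadata_path)
    table = table.set_index("probe_set_id")
    missing_meta = [c for c in table.columns if c not in arrays.index]
    if missing_meta:
        raise ParseError(f"{metadata_path}: no metadata for arrays {missing_meta}")
    expr = ExpressionMatrix(values=table[list(arrays.index)].astype(float),
                            arrays=arrays)
    expr.validate()
    return expr


def write_truth(truth: SimTruth, path) -> None:
    rows = [
        {"probe_set_id": g, "class": "over" if g in truth.over_genes else "under",
         "log2_shift": truth.shifts[g]}
        for g in sorted(truth.shifts)
    ]
    pd.DataFrame(rows, columns=["probe_set_id", "class", "log2_shift"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in ("probe_set_id", "class", "log2_shift")
               if c not in truth.columns]
    if missing:
        raise ParseError(f"{path}: truth table missing columns {missing}")
    return truth


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path) -> frozenset:
    lines = Path(path).read_text().splitlines()
    return frozenset(line.strip() for line in lines if line.strip())


def write_sim_config(config: SimConfig, path) -> None:
    payload = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_sim_config(path) -> SimConfig:
    payload = yaml.safe_load(Path(path).read_text())
    for key in ("tissues", "protocols"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return SimConfig(**payload)
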