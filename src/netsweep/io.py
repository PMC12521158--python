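"""Plain-text readers and writers for every pipeline artifact.

Formats: per-subject time series as TSV (T rows x N ROI columns, header
row of ROI labels), clinical tables as CSV, connectivity matrices as
labeled N x N CSV, binary graphs as edge-list TSV or 0/1 adjacency CSV,
and YAML/JSON configuration files. All writers round-trip exactly
through their paired readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from netsweep.clinical import CLINICAL_COLUMNS
from netsweep.connectivity import ConnectivityMatrix, RoiTimeSeries
from netsweep.graphs import BinaryGraph

__all__ = [
    "read_clinical_csv",
    "read_config",
    "read_connectivity_csv",
    "read_timeseries_dir",
    "read_timeseries_tsv",
    "write_clinical_csv",
    "write_connectivity_csv",
    "write_graph_adjacency_csv",
    "write_graph_edgelist",
    "write_json",
    "write_timeseries_tsv",
]


def write_timeseries_tsv(ts: RoiTimeSeries, path) -> None:
    df = pd.DataFrame(ts.values, columns=ts.roi_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path, subject_id: str | None = None) -> RoiTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(subject_id or path.stem, df.to_numpy(dtype=float),
                         list(df.columns))


def read_timeseries_dir(directory) -> list[RoiTimeSeries]:
    """All *.tsv files of a directory, subject id = file stem, sorted."""
    files = sorted(Path(directory).glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no .tsv time series under {directory}")
    return [read_timeseries_tsv(f) for f in files]


def write_clinical_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns
               and c != "group"]
    if missing:
        raise ValueError(
            f"clinical table {path} missing column(s): {missing}")
    return df


def check_cohort_alignment(
    time_series: list[RoiTimeSeries], clinical: pd.DataFrame
) -> None:
    """Raise listing subjects present on only one side."""
    ts_ids = {t.subject_id for t in time_series}
    clin_ids = set(clinical["subject_id"])
    orphans = sorted(ts_ids ^ clin_ids)
    if orphans:
        raise ValueError(
            f"time series / clinical table mismatch; orphans: {orphans}")


def write_connectivity_csv(fc: ConnectivityMatrix, path) -> None:
    df = pd.DataFrame(fc.r, index=fc.roi_labels, columns=fc.roi_labels)
    df.to_csv(path)  # default repr formatting round-trips doubles exactly


def read_connectivity_csv(path, subject_id: str | None = None
                          ) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return ConnectivityMatrix(subject_id or path.stem,
                              df.to_numpy(dtype=float), list(df.columns))


def write_graph_edgelist(g: BinaryGraph, path,
                         labels: list[str] | None = None) -> None:
    edges = g.edge_list()
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\n")
        for i, j in edges:
            a = labels[i] if labels else str(i)
            b = labels[j] if labels else str(j)
            fh.write(f"{a}\t{b}\n")


def write_graph_adjacency_csv(g: BinaryGraph, path,
                              labels: list[str] | None = None) -> None:
    labels = labels or [str(i) for i in range(g.n_nodes)]
    pd.DataFrame(g.adjacency, index=labels, columns=labels).to_csv(path)


def read_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh) or {}
        return json.load(fh)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
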