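"""CSV readers/writers for the tabular dialects the pipeline exchanges."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calcium import TraceMatrix
from .energetics import RestingMeasurement
from .screen import L2FCTable

__all__ = [
    "read_cohort_csv", "write_cohort_csv",
    "read_trace_matrix", "write_trace_matrix",
    "read_l2fc", "read_titration",
]


def read_cohort_csv(path) -> list[RestingMeasurement]:
    """Read a resting-measurement cohort.

    Columns: cell_id, condition, V_mV and either gin_nS or Rin_MOhm
    (auto-converted, g_in[nS] = 1000 / R_in[MOhm])."""
    df = pd.read_csv(path)
    if "gin_nS" in df.columns:
        gin = df["gin_nS"].astype(float)
    elif "Rin_MOhm" in df.columns:
        gin = 1e3 / df["Rin_MOhm"].astype(float)
    else:
        raise ValueError("cohort CSV needs a gin_nS or Rin_MOhm column")
    return [
        RestingMeasurement(V=float(r.V_mV), g_in=float(g),
                           cell_id=str(r.cell_id), condition=str(r.condition))
        for r, g in zip(df.itertuples(index=False), gin)
    ]


def write_cohort_csv(cohort: list[RestingMeasurement], path) -> None:
    pd.DataFrame({
        "cell_id": [m.cell_id for m in cohort],
        "condition": [m.condition for m in cohort],
        "V_mV": [m.V for m in cohort],
        "gin_nS": [m.g_in for m in cohort],
    }).to_csv(path, index=False)


def read_trace_matrix(traces_path, background_path, mask_path=None,
                      fov_id: str = "fov", frame_interval: float = 2.0
                      ) -> TraceMatrix:
    """Read a wide trace CSV (rows = cells, columns = frames; first column is
    the cell id), a one-column background CSV, and an optional mask CSV."""
    tdf = pd.read_csv(traces_path, index_col=0)
    bg = pd.read_csv(background_path).iloc[:, 0].to_numpy(dtype=float)
    if mask_path is not None:
        mask = pd.read_csv(mask_path).iloc[:, 0].to_numpy(dtype=bool)
    else:
        mask = np.ones(len(tdf), dtype=bool)
    return TraceMatrix(fov_id=fov_id, traces=tdf.to_numpy(dtype=float),
                       background=bg, complete_mask=mask,
                       frame_interval=frame_interval,
                       cell_ids=tuple(str(i) for i in tdf.index))


def write_trace_matrix(tm: TraceMatrix, traces_path, background_path,
                       mask_path=None) -> None:
    pd.DataFrame(tm.traces, index=list(tm.cell_ids)).to_csv(traces_path)
    pd.DataFrame({"background": tm.background}).to_csv(background_path,
                                                       index=False)
    if mask_path is not None:
        pd.DataFrame({"complete": tm.complete_mask}).to_csv(mask_path,
                                                            index=False)


def read_l2fc(matrix_path, groups_path) -> L2FCTable:
    """Read a gene x cell-line L2FC matrix (first column = gene ids) and a
    two-column (cell_line, group) map."""
    values = pd.read_csv(matrix_path, index_col=0)
    gdf = pd.read_csv(groups_path)
    groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    return L2FCTable(values=values, groups=groups)


def read_titration(path) -> list[tuple[float, float]]:
    """Read a titration CSV with columns lactate_mM, net_flux."""
    df = pd.read_csv(path)
    return [(float(c), float(f))
            for c, f in zip(df["lactate_mM"], df["net_flux"])]
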