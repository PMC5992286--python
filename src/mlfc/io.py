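"""HDF5/CSV/TSV input-output for cohorts, graphs, and results."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .bands import BandSpec, CouplingMode, band_by_name
from .connectivity import SLFCG
from .simulate import EpochedRecording


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


def write_cohort(path: str | Path, recordings: Sequence[EpochedRecording]) -> None:
    """Write a cohort as one HDF5 file: /subjects/<id>/data with attrs
    fs, group, epoch_len_s."""
    with h5py.File(path, "w") as f:
        subjects = f.create_group("subjects")
        for rec in recordings:
            g = subjects.create_group(rec.subject_id)
            g.create_dataset("data", data=rec.data)
            g.attrs["fs"] = rec.fs
            g.attrs["group"] = rec.group
            g.attrs["epoch_len_s"] = rec.epoch_len_s


def read_cohort(path: str | Path) -> list[EpochedRecording]:
    """Read a cohort HDF5 file; subjects are returned in id order."""
    recs: list[EpochedRecording] = []
    try:
        with h5py.File(path, "r") as f:
            if "subjects" not in f:
                raise ValueError(f"{path}: missing top-level group 'subjects'")
            for sid in sorted(f["subjects"]):
                g = f["subjects"][sid]
                if "data" not in g:
                    raise ValueError(f"{path}: missing dataset /subjects/{sid}/data")
                recs.append(
                    EpochedRecording(
                        subject_id=sid,
                        group=int(g.attrs["group"]),
                        data=g["data"][()],
                        fs=float(g.attrs["fs"]),
                        epoch_len_s=float(g.attrs["epoch_len_s"]),
                    )
                )
    except OSError as err:
        raise ValueError(f"cannot read cohort file {path}: {err}") from err
    return recs


# --------------------------------------------------------------------------
# graphs
# --------------------------------------------------------------------------


def write_subject_graphs(path: str | Path, graphs: Sequence[SLFCG]) -> None:
    """Write one subject's graphs: /graphs/<estimator>/<mode>/W."""
    with h5py.File(path, "w") as f:
        root = f.create_group("graphs")
        for idx, g in enumerate(graphs):
            grp = root.require_group(g.estimator).create_group(g.mode.label)
            grp.create_dataset("W", data=g.W)
            grp.attrs["kind"] = g.mode.kind
            grp.attrs["order"] = idx


def read_subject_graphs(
    path: str | Path, bands: Sequence[BandSpec]
) -> dict[str, list[SLFCG]]:
    """Read a subject graph file back into ordered SLFCG lists, keyed by
    estimator."""
    out: dict[str, list[SLFCG]] = {}
    try:
        with h5py.File(path, "r") as f:
            if "graphs" not in f:
                raise ValueError(f"{path}: missing top-level group 'graphs'")
            for est in f["graphs"]:
                layers = []
                for label in f["graphs"][est]:
                    grp = f["graphs"][est][label]
                    if "W" not in grp:
                        raise ValueError(f"{path}: missing dataset /graphs/{est}/{label}/W")
                    names = label.split(":")
                    mode = CouplingMode(
                        "intra" if len(names) == 1 else "cross",
                        tuple(band_by_name(n, bands) for n in names),
                    )
                    layers.append(
                        (int(grp.attrs["order"]), SLFCG(estimator=est, mode=mode, W=grp["W"][()]))
                    )
                out[est] = [g for _, g in sorted(layers, key=lambda t: t[0])]
    except OSError as err:
        raise ValueError(f"cannot read graph file {path}: {err}") from err
    return out


# --------------------------------------------------------------------------
# edge lists
# --------------------------------------------------------------------------


def matrix_to_edge_tsv(
    W: np.ndarray, path: str | Path, roi_labels: Sequence[str] | None = None
) -> None:
    """Write the upper triangle of a symmetric matrix as a TSV edge list
    (roi_i, roi_j, weight). Weights round-trip exactly (shortest-repr
    float formatting)."""
    W = np.asarray(W)
    iu, ju = np.triu_indices(W.shape[0], k=1)
    lab = (lambda i: roi_labels[i]) if roi_labels is not None else (lambda i: i)
    with open(path, "w") as fh:
        fh.write("roi_i\troi_j\tweight\n")
        for i, j in zip(iu, ju):
            fh.write(f"{lab(i)}\t{lab(j)}\t{float(W[i, j])!r}\n")


def edge_tsv_to_matrix(path: str | Path, n: int) -> np.ndarray:
    """Read a TSV edge list back into an n x n symmetric matrix."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("roi_i", "roi_j", "weight"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    W = np.zeros((n, n))
    W[df["roi_i"], df["roi_j"]] = df["weight"]
    return W + W.T
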