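"""Plain-text input/output for the toolkit's data objects.

Everything round-trips through delimited text or JSON: waveform mixtures
(one waveform per row, optional final integer label column), square
dissimilarity matrices, partitions (one label per line or a JSON array),
2-D embeddings (TSV with header), and VAT orderings/MSTs as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .data import LabeledWaveformSet
from .features import Embedding2D
from .validity import CrispPartition, partition_from_labels
from .vat import VatResult

PathLike = Union[str, Path]


def save_waveforms(path: PathLike, ws: LabeledWaveformSet) -> None:
    """Write a waveform set as delimited text; labels go in a final column."""
    mat = ws.waveforms
    if ws.labels is not None:
        mat = np.column_stack([mat, ws.labels.astype(float)])
    header = f"sampling_rate={ws.sampling_rate} labeled={ws.labels is not None}"
    np.savetxt(path, mat, delimiter="\t", header=header)


def load_waveforms(
    path: PathLike, sampling_rate: Optional[float] = None, labeled: Optional[bool] = None
) -> LabeledWaveformSet:
    """Read a delimited waveform matrix (as written by :func:`save_waveforms`).

    For files from other sources pass ``sampling_rate`` and ``labeled``
    explicitly; otherwise they are recovered from the header comment.
    """
    path = Path(path)
    if sampling_rate is None or labeled is None:
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "sampling_rate=" in first:
            fields = dict(tok.split("=") for tok in first[1:].split())
            sampling_rate = sampling_rate or float(fields["sampling_rate"])
            if labeled is None:
                labeled = fields.get("labeled") == "True"
        else:
            raise ValueError(
                "no header metadata: pass sampling_rate and labeled explicitly"
            )
    mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    labels = None
    if labeled:
        labels = mat[:, -1].astype(int)
        mat = mat[:, :-1]
    return LabeledWaveformSet(mat, sampling_rate, labels)


def save_matrix(path: PathLike, values: np.ndarray) -> None:
    """Write a square numeric matrix as delimited text."""
    np.savetxt(path, np.asarray(values, dtype=float), delimiter="\t")


def load_matrix(path: PathLike) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def save_partition(path: PathLike, partition: CrispPartition, fmt: str = "lines") -> None:
    """Write a partition: one label per line, or a JSON array with ``fmt='json'``."""
    labels = partition.labels.tolist()
    if fmt == "json":
        Path(path).write_text(json.dumps(labels))
    else:
        Path(path).write_text("\n".join(str(v) for v in labels) + "\n")


def load_partition(path: PathLike) -> CrispPartition:
    text = Path(path).read_text().strip()
    if text.startswith("["):
        labels = json.loads(text)
    else:
        labels = [int(line) for line in text.splitlines() if line.strip()]
    return partition_from_labels(labels)


def save_embedding(path: PathLike, emb: Embedding2D, labels=None) -> None:
    """Write an embedding as TSV (x, y, optional label); params as sidecar JSON."""
    cols = [emb.coords]
    header = "x\ty"
    if labels is not None:
        cols.append(np.asarray(labels, dtype=float)[:, None])
        header += "\tlabel"
    np.savetxt(
        path, np.hstack(cols), delimiter="\t", header=header, comments=""
    )
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    sidecar.write_text(json.dumps({"method": emb.method, "params": emb.params}))


def save_vat_json(path: PathLike, v: VatResult) -> None:
    """Write a VAT reordering and MST as JSON {order, edges: [(i, j, w)]}."""
    payload = {
        "order": [int(i) for i in v.order],
        "edges": [[int(a), int(b), float(w)] for a, b, w in v.mst_edges],
    }
    Path(path).write_text(json.dumps(payload))


def index_record(index_name: str, value: float, k: int, n: int) -> dict:
    """A JSON-ready validity-index record."""
    return {"index_name": index_name, "value": float(value), "k": int(k), "n": int(n)}
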