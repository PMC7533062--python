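"""Reading and writing of epochs, connectivity matrices and atlas tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from ampconn.synthcohort import EpochSet

__all__ = [
    "save_epochs",
    "load_epochs",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


def save_epochs(epochs: EpochSet, path_prefix) -> Tuple[Path, Path]:
    """Write the trials x ROI x samples block (.npy) with a JSON sidecar."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    data_path = prefix.with_suffix(".npy")
    meta_path = prefix.with_suffix(".json")
    np.save(data_path, epochs.data)
    meta_path.write_text(
        json.dumps(
            {
                "subject_id": epochs.subject_id,
                "group": epochs.group,
                "sfreq": epochs.sfreq,
                "t0_ms": epochs.t0_ms,
                "roi_labels": list(epochs.roi_labels),
                "shape": list(epochs.data.shape),
            },
            indent=2,
        )
    )
    return data_path, meta_path


def load_epochs(path_prefix) -> EpochSet:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.load(prefix.with_suffix(".npy"))
    return EpochSet(
        subject_id=meta["subject_id"],
        group=meta["group"],
        data=data,
        sfreq=meta["sfreq"],
        t0_ms=meta["t0_ms"],
        roi_labels=meta["roi_labels"],
    )


def write_matrix_tsv(matrix: np.ndarray, labels: Sequence[str], path) -> None:
    """Square matrix as TSV with node labels as header and index."""
    pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t"
    )


def read_matrix_tsv(path) -> Tuple[np.ndarray, List[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
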