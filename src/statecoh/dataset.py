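"""In-memory container and HDF5 I/O for virtual-electrode time series.

A :class:`VirtualElectrodeDataset` holds one ``nodes x samples`` record per
subject per block, with shared sampling rate and node identity across the
whole dataset (the analysis assumes a common node set and fs).

On disk the dataset is a hierarchical array container: one HDF5 group per
subject, one 2-D array per block, with ``fs``, block labels and node ids as
attributes — a generic layout that exported beamformer virtual-electrode
data can be converted into.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = ["VirtualElectrodeDataset"]


@dataclass
class VirtualElectrodeDataset:
    """Node time series for every subject and block.

    Attributes
    ----------
    data : ndarray, shape (n_subjects, n_blocks, n_nodes, n_samples)
    block_labels : sequence of str, condition label per block, in order.
    subject_ids : sequence of str.
    node_ids : sequence of int, atlas ids in row order.
    fs : float, sampling rate in Hz.
    """

    data: np.ndarray
    block_labels: Sequence[str]
    subject_ids: Sequence[str]
    node_ids: Sequence[int]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (subjects, blocks, nodes, samples)")
        n_s, n_b, n_n, _ = self.data.shape
        if len(self.subject_ids) != n_s:
            raise ValueError("subject_ids length mismatch")
        if len(self.block_labels) != n_b:
            raise ValueError("block_labels length mismatch")
        if len(set(self.block_labels)) != n_b:
            raise ValueError("block labels must be unique")
        if len(self.node_ids) != n_n:
            raise ValueError("node_ids length mismatch")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.data.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]

    @property
    def duration(self) -> float:
        """Block duration in seconds."""
        return self.n_samples / self.fs

    def block(self, subject: str, label: str) -> np.ndarray:
        """The ``nodes x samples`` record of one subject/block."""
        s = list(self.subject_ids).index(subject)
        b = list(self.block_labels).index(label)
        return self.data[s, b]

    def save(self, path: str | Path) -> None:
        """Write as HDF5: one group per subject, one array per block."""
        with h5py.File(path, "w") as f:
            f.attrs["fs"] = self.fs
            f.attrs["block_labels"] = list(self.block_labels)
            f.attrs["node_ids"] = np.asarray(self.node_ids, dtype=int)
            for s, sid in enumerate(self.subject_ids):
                grp = f.create_group(str(sid))
                for b, label in enumerate(self.block_labels):
                    d = grp.create_dataset(label, data=self.data[s, b])
                    d.attrs["block_label"] = label

    @classmethod
    def load(cls, path: str | Path) -> "VirtualElectrodeDataset":
        with h5py.File(path, "r") as f:
            fs = float(f.attrs["fs"])
            block_labels = [str(x) for x in f.attrs["block_labels"]]
            node_ids = [int(x) for x in f.attrs["node_ids"]]
            subject_ids = sorted(f.keys())
            if not subject_ids:
                raise ValueError(f"no subjects in {path}")
            arrs = []
            for sid in subject_ids:
                blocks = [np.asarray(f[sid][label]) for label in block_labels]
                shapes = {a.shape for a in blocks}
                if len(shapes) != 1:
                    raise ValueError(
                        f"subject {sid}: inconsistent block shapes {shapes}"
                    )
                arrs.append(np.stack(blocks))
            data = np.stack(arrs)
        return cls(data, block_labels, subject_ids, node_ids, fs)
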