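"""Streamline tract atlas container and I/O.

The atlas is a labelled set of 3-D polylines in world millimetres —
a synthetic analogue of a population-average tractography atlas in
which streamlines are grouped into named tracts.  Two on-disk formats
are supported: TRK (via ``nibabel.streamlines``, tract label carried as
a per-streamline property) and a plain JSON-lines fallback with one
object per streamline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import ReferenceGrid

__all__ = ["TractAtlas"]


@dataclass
class TractAtlas:
    """Labelled streamlines.

    Attributes
    ----------
    streamlines : list of (n_i, 3) float arrays
        Ordered points in world mm; every polyline has >= 2 points.
    tract_labels : (n_streamlines,) int array
        Integer tract label in ``1..n_tracts`` per streamline.
    tract_names : dict, optional
        Optional label -> name mapping.
    """

    streamlines: list[np.ndarray]
    tract_labels: np.ndarray
    tract_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        self.tract_labels = np.asarray(self.tract_labels, dtype=int)
        if len(self.streamlines) != len(self.tract_labels):
            raise ValueError("one tract label per streamline required")
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError("each streamline must be an (n>=2, 3) point array")
        labels = np.unique(self.tract_labels)
        expected = np.arange(1, labels.max() + 1) if labels.size else labels
        if labels.size == 0 or not np.array_equal(labels, expected):
            raise ValueError("tract labels must cover 1..T with no empty tract")

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)

    @property
    def n_tracts(self) -> int:
        return int(self.tract_labels.max())

    def tract(self, label: int) -> list[np.ndarray]:
        """Streamlines belonging to one tract."""
        return [s for s, l in zip(self.streamlines, self.tract_labels) if l == label]

    def tract_name(self, label: int) -> str:
        return self.tract_names.get(int(label), f"tract_{int(label)}")

    # ------------------------------------------------------------------ I/O

    def save_trk(self, path, grid: ReferenceGrid) -> None:
        """Write as TRK with the grid supplying the reference header."""
        tractogram = nib.streamlines.Tractogram(
            self.streamlines,
            data_per_streamline={
                "tract_label": self.tract_labels[:, None].astype(np.float32)
            },
            affine_to_rasmm=np.eye(4),
        )
        header = {
            nib.streamlines.trk.Field.VOXEL_TO_RASMM: grid.affine.astype(np.float32),
            nib.streamlines.trk.Field.VOXEL_SIZES: np.asarray(
                grid.voxel_size, np.float32
            ),
            nib.streamlines.trk.Field.DIMENSIONS: np.asarray(grid.shape, np.int16),
        }
        nib.streamlines.save(
            nib.streamlines.TrkFile(tractogram, header=header), str(path)
        )

    @classmethod
    def load_trk(cls, path) -> "TractAtlas":
        trk = nib.streamlines.load(str(path))
        tractogram = trk.tractogram.to_world()
        labels = np.asarray(
            tractogram.data_per_streamline["tract_label"], float
        ).ravel()
        return cls(
            streamlines=[np.asarray(s, float) for s in tractogram.streamlines],
            tract_labels=np.rint(labels).astype(int),
        )

    def save_jsonl(self, path) -> None:
        """JSON-lines fallback: one {"tract_label", "points"} object per line."""
        with open(path, "w") as fh:
            for label, sl in zip(self.tract_labels, self.streamlines):
                fh.write(
                    json.dumps(
                        {"tract_label": int(label), "points": sl.tolist()},
                        separators=(",", ":"),
                    )
                    + "\n"
                )

    @classmethod
    def load_jsonl(cls, path) -> "TractAtlas":
        streamlines, labels = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                streamlines.append(np.asarray(obj["points"], float))
                labels.append(int(obj["tract_label"]))
        return cls(streamlines=streamlines, tract_labels=np.asarray(labels))

    @classmethod
    def load(cls, path) -> "TractAtlas":
        path = Path(path)
        if path.suffix == ".trk":
            return cls.load_trk(path)
        return cls.load_jsonl(path)
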