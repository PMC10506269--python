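"""Sequence I/O, one-hot encoding and dataset containers.

Sequences are stored length-major internally: a sequence of length ``L``
becomes an ``L x 4`` matrix with channel order ``(A, C, G, T)``.  The
transposed ``4 x L`` orientation is accepted on import and produced on
request for interoperability.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT"
#: base -> channel index; 'N' has no channel and encodes to an all-zero row
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "DnaSequence",
    "DatasetSplit",
    "Dataset",
    "EncodingError",
    "MalformedMatrixError",
    "one_hot_encode",
    "decode_one_hot",
    "coerce_length_major",
    "split_train_val",
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "write_label_table",
    "save_dataset",
    "load_dataset",
]


class EncodingError(ValueError):
    """A sequence contains a symbol outside {A, C, G, T, N}."""


class MalformedMatrixError(ValueError):
    """A purported one-hot matrix violates the row-sum or shape contract."""


@dataclasses.dataclass(frozen=True)
class DnaSequence:
    """A named DNA sequence over {A, C, G, T, N}, stored upper-case."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        if len(self.bases) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, sym in enumerate(self.bases):
            if sym not in "ACGTN":
                raise EncodingError(
                    f"sequence {self.id!r}: invalid symbol {sym!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.bases)


def one_hot_encode(seq: DnaSequence | str) -> np.ndarray:
    """Encode a sequence as an ``L x 4`` binary matrix, channels ``(A,C,G,T)``.

    ``N`` maps to an all-zero row.  Raises :class:`EncodingError` naming the
    offending position for any other symbol.
    """
    if isinstance(seq, str):
        seq = DnaSequence(id="<anonymous>", bases=seq)
    mat = np.zeros((len(seq), 4), dtype=np.uint8)
    for t, sym in enumerate(seq.bases):
        if sym != "N":
            mat[t, BASE_INDEX[sym]] = 1
    return mat


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to ``N``."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise MalformedMatrixError(f"expected L x 4 matrix, got shape {matrix.shape}")
    sums = matrix.sum(axis=1)
    bad = np.nonzero(sums > 1)[0]
    if bad.size:
        raise MalformedMatrixError(f"row {bad[0]} has sum {sums[bad[0]]} > 1")
    out = []
    for row, s in zip(matrix, sums):
        out.append("N" if s == 0 else ALPHABET[int(np.argmax(row))])
    return "".join(out)


def coerce_length_major(matrix: np.ndarray, orientation: str | None = None) -> np.ndarray:
    """Return a length-major ``L x 4`` view of a one-hot matrix.

    Accepts either ``L x 4`` or the transposed ``4 x L`` layout, detecting the
    orientation by which axis has size 4.  Square ``4 x 4`` inputs are
    ambiguous and require an explicit ``orientation`` of ``"length_major"``
    or ``"channel_major"``.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise MalformedMatrixError(f"expected a 2-D matrix, got shape {matrix.shape}")
    if orientation == "length_major":
        pass
    elif orientation == "channel_major":
        matrix = matrix.T
    elif orientation is None:
        if matrix.shape == (4, 4):
            raise MalformedMatrixError(
                "4 x 4 matrix is ambiguous; pass orientation="
                "'length_major' or 'channel_major'"
            )
        if matrix.shape[1] == 4:
            pass
        elif matrix.shape[0] == 4:
            matrix = matrix.T
        else:
            raise MalformedMatrixError(f"no axis of size 4 in shape {matrix.shape}")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if matrix.shape[1] != 4:
        raise MalformedMatrixError(f"coerced matrix has shape {matrix.shape}")
    return matrix


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive train/validation index partition."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        train = np.asarray(self.train_idx, dtype=np.int64)
        val = np.asarray(self.val_idx, dtype=np.int64)
        object.__setattr__(self, "train_idx", train)
        object.__setattr__(self, "val_idx", val)
        n = train.size + val.size
        union = np.union1d(train, val)
        if union.size != n or union[0] != 0 or union[-1] != n - 1:
            raise ValueError("train/val indices must partition 0..n-1")


def split_train_val(n: int, frac: float = 0.92, seed: int = 0) -> DatasetSplit:
    """Shuffle ``0..n-1`` and split with ``round-half-up(frac * n)`` training rows."""
    if n < 2:
        raise ValueError(f"need n >= 2 to form both partitions, got n={n}")
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    # round half up, e.g. 0.92 * 10 = 9.2 -> 9; 0.5 offsets round to the upper int
    n_train = int(np.floor(frac * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return DatasetSplit(train_idx=perm[:n_train], val_idx=perm[n_train:], seed=seed)


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read a FASTA file into :class:`DnaSequence` records, in file order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            records.append(DnaSequence(id=rec.id, bases=str(rec.seq)))
        except ValueError as exc:
            raise EncodingError(f"record {i} ({rec.id!r}): {exc}") from exc
    return records


def write_fasta(path: str | Path, sequences: Iterable[DnaSequence]) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for start in range(0, len(seq.bases), 80):
                fh.write(seq.bases[start : start + 80] + "\n")


def read_label_table(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a TSV label file: header ``id<TAB>class1...``, rows of 0/1.

    Returns ``(sequence_ids, labels, class_names)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"label file {path} needs an id column and >= 1 class column")
        class_names = header[1:]
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            ids.append(fields[0])
            try:
                row = [int(v) for v in fields[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer label") from exc
            if any(v not in (0, 1) for v in row):
                raise ValueError(f"{path}:{lineno}: labels must be 0 or 1")
            rows.append(row)
    return ids, np.asarray(rows, dtype=np.uint8), class_names


def write_label_table(
    path: str | Path, ids: Sequence[str], labels: np.ndarray, class_names: Sequence[str]
) -> None:
    labels = np.asarray(labels)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(class_names) + "\n")
        for sid, row in zip(ids, labels):
            fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


@dataclasses.dataclass
class Dataset:
    """Encoded sequences plus labels; the on-disk unit moved between commands."""

    x: np.ndarray  # (n, L, 4) uint8 one-hot
    y: np.ndarray  # (n, C) uint8
    class_names: list[str]
    ids: list[str]
    split: DatasetSplit | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.uint8)
        self.y = np.asarray(self.y, dtype=np.uint8)
        if self.x.ndim != 3 or self.x.shape[2] != 4:
            raise ValueError(f"x must be (n, L, 4), got {self.x.shape}")
        if self.y.ndim != 2 or self.y.shape[0] != self.x.shape[0]:
            raise ValueError(
                f"y must be (n, C) with n={self.x.shape[0]}, got {self.y.shape}"
            )
        if len(self.class_names) != self.y.shape[1]:
            raise ValueError("class_names length must equal label columns")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def length(self) -> int:
        return self.x.shape[1]

    @property
    def n_classes(self) -> int:
        return self.y.shape[1]


def save_dataset(path: str | Path, ds: Dataset) -> None:
    """Persist a dataset (and optional split) to an ``.npz`` container."""
    payload = {
        "x": ds.x,
        "y": ds.y,
        "class_names": np.asarray(ds.class_names, dtype=object),
        "ids": np.asarray(ds.ids, dtype=object),
    }
    if ds.split is not None:
        payload["train_idx"] = ds.split.train_idx
        payload["val_idx"] = ds.split.val_idx
        payload["split_seed"] = np.asarray(ds.split.seed)
    np.savez_compressed(path, **payload)


def load_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset container not found: {path}")
    with np.load(path, allow_pickle=True) as z:
        split = None
        if "train_idx" in z:
            split = DatasetSplit(
                train_idx=z["train_idx"],
                val_idx=z["val_idx"],
                seed=int(z["split_seed"]),
            )
        return Dataset(
            x=z["x"],
            y=z["y"],
            class_names=[str(c) for c in z["class_names"]],
            ids=[str(i) for i in z["ids"]],
            split=split,
        )
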