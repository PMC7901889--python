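"""On-disk artifacts and epoch selection.

All file formats are header-first delimited text; comma and tab/whitespace
are both accepted on read, tab is emitted on write.  Indices are 0-based
and intervals half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError

LINK_COLUMNS = ["subject_id", "node_a", "node_b", "hemisphere_pair", "d_mm", "W_s"]

_HEMI_TOKENS = {
    "left": "left", "l": "left", "lh": "left",
    "right": "right", "r": "right", "rh": "right",
}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class TimeSeriesSet:
    """Sampled signals for all nodes of one subject.

    ``samples`` has one row per time point and one column per node;
    ``sampling_period`` is in seconds.
    """

    subject_id: str
    sampling_period: float
    node_ids: list[str]
    samples: np.ndarray
    # optional per-subject node geometry (anatomical variability); when
    # present the analysis uses these positions instead of a shared table
    nodes: "NodeTable | None" = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D matrix")
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")
        if self.samples.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if len(self.node_ids) != self.samples.shape[1]:
            raise ValueError("node_ids must match the number of columns")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples * self.sampling_period

    def column(self, node_id: str) -> np.ndarray:
        return self.samples[:, self.node_ids.index(node_id)]

    def subset(self, node_ids: Sequence[str]) -> "TimeSeriesSet":
        idx = [self.node_ids.index(n) for n in node_ids]
        nodes = self.nodes.subset(node_ids) if self.nodes is not None else None
        return TimeSeriesSet(self.subject_id, self.sampling_period,
                             list(node_ids), self.samples[:, idx],
                             nodes=nodes)


@dataclass
class NodeTable:
    """Node identifiers, atlas labels, hemispheres and 3-D positions (mm)."""

    node_ids: list[str]
    labels: list[str]
    hemispheres: list[str]
    positions: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise FormatError("duplicate node ids in node table")
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be an (n, 3) matrix")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")
        bad = set(self.hemispheres) - {"left", "right"}
        if bad:
            raise FormatError(f"unknown hemisphere token(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.node_ids)

    def index(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def position(self, node_id: str) -> np.ndarray:
        return self.positions[self.index(node_id)]

    def hemisphere(self, node_id: str) -> str:
        return self.hemispheres[self.index(node_id)]

    def distance_matrix(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))

    def min_pair_distance(self) -> float:
        dm = self.distance_matrix()
        return float(dm[np.triu_indices(len(self), k=1)].min())

    def subset(self, node_ids: Sequence[str]) -> "NodeTable":
        idx = [self.index(n) for n in node_ids]
        return NodeTable([self.node_ids[i] for i in idx],
                         [self.labels[i] for i in idx],
                         [self.hemispheres[i] for i in idx],
                         self.positions[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_id": self.node_ids, "label": self.labels,
            "hemisphere": self.hemispheres,
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2],
        })


@dataclass(frozen=True)
class Epoch:
    """Half-open artifact-free segment, in sample indices."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    def duration(self, sampling_period: float) -> float:
        return self.n_samples * sampling_period


# ---------------------------------------------------------------------------
# readers / writers


def _split_line(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def _read_rows(path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rows.append(_split_line(line))
    return rows


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def read_series_matrix(path, sampling_period: float,
                       subject_id: str | None = None) -> TimeSeriesSet:
    """Read a delimited numeric matrix, one column per node.

    An optional single header row carries node identifiers; otherwise nodes
    are named ``n001``, ``n002``, ...  Trailing blank lines are ignored.
    """
    path = Path(path)
    rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty series file")
    start = 0
    n_cols = len(rows[0])
    if any(not _is_number(tok) for tok in rows[0]):
        node_ids = [str(t) for t in rows[0]]
        start = 1
    else:
        node_ids = [f"n{i + 1:03d}" for i in range(n_cols)]
    data_rows = rows[start:]
    if not data_rows:
        raise FormatError(f"{path}: no data rows")
    values = np.empty((len(data_rows), n_cols))
    for i, row in enumerate(data_rows):
        if len(row) != n_cols:
            raise FormatError(
                f"{path}: row {i + start + 1} has {len(row)} fields, "
                f"expected {n_cols}")
        for j, tok in enumerate(row):
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {tok!r} at row "
                    f"{i + start + 1}, column {j + 1}") from None
    return TimeSeriesSet(subject_id or path.stem, sampling_period,
                         node_ids, values)


def write_series_matrix(ts: TimeSeriesSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ts.node_ids) + "\n")
        np.savetxt(fh, ts.samples, fmt="%.10g", delimiter="\t")


def read_node_table(path) -> NodeTable:
    """Read a node table with columns node_id, label, hemisphere, x, y, z."""
    path = Path(path)
    rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty node table")
    if rows and not _is_number(rows[0][-1]):  # header row
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: empty node table")
    ids, labels, hemis, pos = [], [], [], []
    for i, row in enumerate(rows):
        if len(row) != 6:
            raise FormatError(
                f"{path}: row {i + 1} has {len(row)} fields, expected 6 "
                "(node_id, label, hemisphere, x, y, z)")
        nid, label, hemi = row[0], row[1], row[2].lower()
        if hemi not in _HEMI_TOKENS:
            raise FormatError(f"{path}: unknown hemisphere token {row[2]!r} "
                              f"at row {i + 1}")
        if nid in ids:
            raise FormatError(f"{path}: duplicate node id {nid!r}")
        try:
            xyz = [float(t) for t in row[3:6]]
        except ValueError:
            raise FormatError(f"{path}: non-numeric coordinate at row "
                              f"{i + 1}") from None
        ids.append(nid)
        labels.append(label)
        hemis.append(_HEMI_TOKENS[hemi])
        pos.append(xyz)
    return NodeTable(ids, labels, hemis, np.array(pos))


def write_node_table(nodes: NodeTable, path) -> None:
    nodes.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_link_table(links: pd.DataFrame, path) -> None:
    """Write a link table; unobservable links get an empty ``W_s`` field."""
    df = links.loc[:, LINK_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")


def read_link_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"[\t,]", engine="python")
    missing = set(LINK_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: link table missing columns {sorted(missing)}")
    df["W_s"] = pd.to_numeric(df["W_s"], errors="coerce").astype(float)
    df["d_mm"] = pd.to_numeric(df["d_mm"], errors="coerce").astype(float)
    for c in ("subject_id", "node_a", "node_b", "hemisphere_pair"):
        df[c] = df[c].astype(str)
    return df.loc[:, LINK_COLUMNS]


def write_matrix(values: np.ndarray, path, col_labels=None) -> None:
    """Dump a numeric matrix (e.g. an r/p diagram) as tab-delimited text."""
    with open(path, "w") as fh:
        if col_labels is not None:
            fh.write("\t".join(str(c) for c in col_labels) + "\n")
        np.savetxt(fh, np.asarray(values), fmt="%.10g", delimiter="\t")


# ---------------------------------------------------------------------------
# epoch selection / trimming


def _trim_symmetric(epoch: Epoch, n_target: int) -> Epoch:
    """Remove samples equally from both ends; the odd leftover sample is
    taken from the end."""
    excess = epoch.n_samples - n_target
    if excess < 0:
        raise ValueError("cannot trim an epoch below its own length")
    front = excess // 2
    back = excess - front
    return Epoch(epoch.start_index + front, epoch.end_index - back)


def _n_for(seconds: float, sampling_period: float) -> int:
    return int(round(seconds / sampling_period))


def select_and_trim_epochs(epochs: Iterable[Epoch],
                           sampling_period: float) -> list[Epoch]:
    """Apply the duration-standardization rules to a subject's epochs.

    Longest epoch >= 240 s: trim it symmetrically to 240 s.  Between 180
    and 240 s: trim to 180 s.  Below 180 s: keep the longest epoch whole
    and trim the second-longest to supply the remainder, totalling 180 s,
    or 160 s when the two together cannot reach 180 s.  Below a combined
    160 s the subject is excluded.
    """
    epochs = sorted(epochs, key=lambda e: e.start_index)
    for a, b in zip(epochs, epochs[1:]):
        if b.start_index < a.end_index:
            raise ValueError("epochs overlap")
    if not epochs:
        raise ValueError("no epochs supplied")
    T = sampling_period
    by_len = sorted(epochs, key=lambda e: e.n_samples, reverse=True)
    longest = by_len[0]
    t1 = longest.duration(T)
    eps = 1e-9
    if t1 >= 240 - eps:
        return [_trim_symmetric(longest, _n_for(240, T))]
    if t1 >= 180 - eps:
        return [_trim_symmetric(longest, _n_for(180, T))]
    second = by_len[1] if len(by_len) > 1 else None
    combined = t1 + (second.duration(T) if second else 0.0)
    if combined >= 180 - eps:
        target_s = 180.0
    elif combined >= 160 - eps:
        target_s = 160.0
    else:
        raise InsufficientDataError(
            f"two longest epochs total {combined:.1f} s < 160 s; "
            "subject excluded")
    n_target = _n_for(target_s, T)
    n1 = min(longest.n_samples, n_target)
    out = [_trim_symmetric(longest, n1)]
    remainder = n_target - n1
    if remainder > 0:
        out.append(_trim_symmetric(second, remainder))
    return sorted(out, key=lambda e: e.start_index)


def extract_epochs(ts: TimeSeriesSet, epochs: Sequence[Epoch]) -> TimeSeriesSet:
    """Concatenate the given epochs of a series set into one sequence."""
    parts = [ts.samples[e.start_index:e.end_index] for e in epochs]
    return TimeSeriesSet(ts.subject_id, ts.sampling_period, list(ts.node_ids),
                         np.concatenate(parts, axis=0), nodes=ts.nodes)
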