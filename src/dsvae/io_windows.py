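"""Data model and I/O for multivariate component timecourses.

A subject's data is an ``N components x T timesteps`` real matrix (for
example ICA component timecourses extracted from rs-fMRI, where the paper
pipeline of interest produces N = 53 components at a 2 s sampling interval).
This module holds the container types, delimited-text / HDF5 readers and
writers, per-component normalization, sliding-window extraction, and
subject-level train/val/test splitting.

Coordinates are 0-based; windows are half-open intervals
``[start, start + width)`` over timesteps.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

DIAGNOSES = ("control", "patient")
SPLITS = ("train", "val", "test")

#: Fixed leading columns of an embedding table file.
EMBEDDING_KEY_COLUMNS = ("subject_id", "window_start", "split", "diagnosis")


def _clean_optional(value) -> float | None:
    """Normalize missing covariates (None/NaN/empty) to None."""
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(v) else v


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's component-timecourse matrix plus phenotype labels.

    Parameters
    ----------
    subject_id : opaque identifier, unique within a dataset.
    diagnosis : ``"patient"`` or ``"control"``.
    data : real matrix of shape (n_components, n_timesteps), finite.
    age : years, optional.
    cognitive_score : composite neurocognitive score, optional
        (lower = worse performance).
    sampling_interval : seconds between consecutive timesteps (TR).
    """

    subject_id: str
    diagnosis: str
    data: np.ndarray
    age: float | None = None
    cognitive_score: float | None = None
    sampling_interval: float = 2.0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(
                f"subject {self.subject_id!r}: data must be 2-D "
                f"(components x timesteps), got shape {data.shape}"
            )
        n, t = data.shape
        if n < 2:
            raise ValueError(f"subject {self.subject_id!r}: need >= 2 components, got {n}")
        if t < 1:
            raise ValueError(f"subject {self.subject_id!r}: need >= 1 timestep, got {t}")
        bad = ~np.isfinite(data)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"subject {self.subject_id!r}: non-finite value at "
                f"component {i}, timestep {j}"
            )
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"subject {self.subject_id!r}: diagnosis must be one of "
                f"{DIAGNOSES}, got {self.diagnosis!r}"
            )
        if self.sampling_interval <= 0:
            raise ValueError(f"subject {self.subject_id!r}: sampling_interval must be > 0")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "age", _clean_optional(self.age))
        object.__setattr__(self, "cognitive_score", _clean_optional(self.cognitive_score))

    @property
    def n_components(self) -> int:
        return self.data.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``width`` timesteps per window, ``stride``
    timesteps between consecutive window starts.

    The defaults (width 32, stride 4) correspond to 64 s windows spaced 8 s
    apart at a 2 s sampling interval.
    """

    width: int = 32
    stride: int = 4

    def __post_init__(self):
        if int(self.width) != self.width or self.width < 2:
            raise ValueError(f"width must be an integer >= 2, got {self.width}")
        if int(self.stride) != self.stride or self.stride < 1:
            raise ValueError(f"stride must be an integer >= 1, got {self.stride}")

    def width_seconds(self, sampling_interval: float = 2.0) -> float:
        return self.width * sampling_interval

    def stride_seconds(self, sampling_interval: float = 2.0) -> float:
        return self.stride * sampling_interval


@dataclass(frozen=True)
class Window:
    """An ``N x width`` slice of one subject's timeseries.

    ``data`` equals the source record's columns ``[start, start + width)``.
    """

    subject_id: str
    start: int
    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("window data must be 2-D (components x width)")
        if self.start < 0:
            raise ValueError("window start must be >= 0")
        object.__setattr__(self, "data", data)

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_components(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class DatasetSplit:
    """Subject-level assignment to train/val/test.

    Every subject appears exactly once; all windows of a subject inherit its
    split, so no subject's windows can leak across splits.
    """

    assignment: Mapping[str, str]

    def __post_init__(self):
        for sid, split in self.assignment.items():
            if split not in SPLITS:
                raise ValueError(f"subject {sid!r}: unknown split {split!r}")
        object.__setattr__(self, "assignment", dict(self.assignment))

    def __getitem__(self, subject_id: str) -> str:
        return self.assignment[subject_id]

    def subjects_in(self, split: str) -> list[str]:
        return sorted(s for s, v in self.assignment.items() if v == split)

    def counts(self) -> dict[str, int]:
        return {s: len(self.subjects_in(s)) for s in SPLITS}


# ---------------------------------------------------------------------------
# Timecourse / metadata I/O
# ---------------------------------------------------------------------------

def _read_matrices(data_path: Path, subject_ids: Sequence[str]) -> dict[str, np.ndarray]:
    data_path = Path(data_path)
    wanted = set(subject_ids)
    out: dict[str, np.ndarray] = {}
    if data_path.is_dir():
        found = {p.stem: p for p in sorted(data_path.glob("*.tsv"))}
        extra = sorted(set(found) - wanted)
        missing = sorted(wanted - set(found))
        if missing:
            raise FileNotFoundError(
                f"no timecourse matrix for subject(s) {missing} under {data_path}"
            )
        if extra:
            raise ValueError(
                f"timecourse matrix for subject(s) {extra} not present in metadata"
            )
        for sid in subject_ids:
            out[sid] = np.loadtxt(found[sid], delimiter="\t", ndmin=2)
    elif data_path.suffix in {".h5", ".hdf5"}:
        with h5py.File(data_path, "r") as f:
            keys = set(f.keys())
            missing = sorted(wanted - keys)
            extra = sorted(keys - wanted)
            if missing:
                raise FileNotFoundError(
                    f"no timecourse dataset for subject(s) {missing} in {data_path}"
                )
            if extra:
                raise ValueError(
                    f"timecourse dataset for subject(s) {extra} not present in metadata"
                )
            for sid in subject_ids:
                out[sid] = np.asarray(f[sid], dtype=float)
    else:
        raise ValueError(
            f"data_path must be a directory of per-subject TSVs or an HDF5 "
            f"container, got {data_path}"
        )
    return out


def load_timecourses(data_path, metadata_path) -> list[SubjectRecord]:
    """Load one :class:`SubjectRecord` per metadata row.

    ``data_path`` is either a directory with one ``<subject_id>.tsv`` matrix
    per subject (rows = components, columns = timesteps) or a single HDF5
    file with one dataset per subject. ``metadata_path`` is a CSV with
    columns ``subject_id, diagnosis`` and optionally
    ``age, cognitive_score, sampling_interval``.

    All subjects must share the same number of components; a subject present
    in only one of the two sources is a hard error naming the subject.
    Missing age/cognitive_score stay missing (None), never imputed.
    """
    meta = pd.read_csv(metadata_path, dtype={"subject_id": str})
    for col in ("subject_id", "diagnosis"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    ids = meta["subject_id"].tolist()
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate subject_id(s) in metadata: {dup}")
    if not ids:
        return []
    matrices = _read_matrices(Path(data_path), ids)

    n_components = {sid: m.shape[0] for sid, m in matrices.items()}
    distinct = sorted(set(n_components.values()))
    if len(distinct) > 1:
        raise ValueError(
            f"all subjects must share the same number of components; "
            f"found {distinct} (e.g. "
            + ", ".join(f"{s}: {n}" for s, n in list(n_components.items())[:4])
            + ")"
        )

    records = []
    for row in meta.itertuples(index=False):
        d = row._asdict()
        records.append(
            SubjectRecord(
                subject_id=d["subject_id"],
                diagnosis=d["diagnosis"],
                data=matrices[d["subject_id"]],
                age=_clean_optional(d.get("age")),
                cognitive_score=_clean_optional(d.get("cognitive_score")),
                sampling_interval=float(d.get("sampling_interval") or 2.0),
            )
        )
    return records


def write_timecourses(records: Iterable[SubjectRecord], data_dir, metadata_path) -> None:
    """Write per-subject TSV matrices and the metadata CSV."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        np.savetxt(data_dir / f"{rec.subject_id}.tsv", rec.data, delimiter="\t")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "diagnosis": rec.diagnosis,
                "age": rec.age,
                "cognitive_score": rec.cognitive_score,
                "sampling_interval": rec.sampling_interval,
            }
        )
    pd.DataFrame(rows).to_csv(metadata_path, index=False)


# ---------------------------------------------------------------------------
# Normalization and windowing
# ---------------------------------------------------------------------------

def normalize_components(record: SubjectRecord, method: str = "zscore") -> SubjectRecord:
    """Per-component normalization over the full timeseries (not per window).

    ``zscore`` gives each component row mean 0 and variance 1 using the
    population convention (ddof=0); ``none`` is the identity. A component
    with zero variance under ``zscore`` is an error naming the component.
    """
    if method == "none":
        return record
    if method != "zscore":
        raise ValueError(f"unknown normalization method {method!r}")
    data = record.data
    mean = data.mean(axis=1, keepdims=True)
    std = data.std(axis=1, ddof=0, keepdims=True)
    zero = np.flatnonzero(std[:, 0] == 0)
    if zero.size:
        raise ValueError(
            f"subject {record.subject_id!r}: component {int(zero[0])} has zero "
            f"variance; cannot z-score"
        )
    return dataclasses.replace(record, data=(data - mean) / std)


def make_windows(record: SubjectRecord, spec: WindowSpec = WindowSpec()) -> list[Window]:
    """Extract overlapping windows with starts 0, stride, 2*stride, ...

    Returns exactly ``floor((T - width) / stride) + 1`` windows. A subject
    shorter than one window is rejected (never padded).
    """
    T, W, S = record.n_timesteps, spec.width, spec.stride
    if T < W:
        raise ValueError(
            f"subject {record.subject_id!r}: timeseries of length {T} is "
            f"shorter than one window (width {W})"
        )
    return [
        Window(record.subject_id, s, record.data[:, s : s + W].copy())
        for s in range(0, T - W + 1, S)
    ]


def windows_to_array(windows: Sequence[Window]) -> np.ndarray:
    """Stack windows into a (n_windows, n_components, width) array."""
    if not windows:
        raise ValueError("empty window list")
    widths = {w.width for w in windows}
    comps = {w.n_components for w in windows}
    if len(widths) != 1 or len(comps) != 1:
        raise ValueError("windows must share width and component count")
    return np.stack([w.data for w in windows])


# ---------------------------------------------------------------------------
# Subject-level splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of n items to len(fractions) bins; ties broken by
    lower bin index."""
    quota = n * fractions
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = n - base.sum()
    # stable sort on (-remainder, index): larger remainders first, low index wins ties
    order = sorted(range(len(fractions)), key=lambda i: (-remainder[i], i))
    for i in order[:short]:
        base[i] += 1
    return base


def split_subjects(
    records: Sequence[SubjectRecord],
    fractions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Deterministic, diagnosis-stratified subject-level split.

    The assignment is a function of (subject_ids, fractions, seed) only —
    input order is irrelevant. Within each diagnosis group the split sizes
    follow the largest-remainder rounding of ``len(group) * fractions``, so
    each split's patient/control ratio is within one subject of the global
    ratio.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,):
        raise ValueError("fractions must be three numbers (train, val, test)")
    if (fr < 0).any():
        raise ValueError("fractions must be non-negative")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got sum {fr.sum()!r})")

    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in records")
    by_diag: dict[str, list[str]] = {}
    for r in records:
        by_diag.setdefault(r.diagnosis, []).append(r.subject_id)

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for diag in sorted(by_diag):
        group = sorted(by_diag[diag])
        perm = rng.permutation(len(group))
        counts = _largest_remainder(len(group), fr)
        labels = np.repeat(SPLITS, counts)
        for idx, label in zip(perm, labels):
            assignment[group[idx]] = label

    split = DatasetSplit(assignment)
    for frac, name in zip(fr, SPLITS):
        if frac > 0 and not split.subjects_in(name):
            raise ValueError(
                f"requested a nonempty {name!r} split (fraction {frac}) but no "
                f"subject was assigned to it; need more subjects"
            )
    return split


# ---------------------------------------------------------------------------
# Embedding tables
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingTable:
    """Per-window context embeddings with provenance labels.

    One row per window: (subject_id, window_start, split, diagnosis) plus a
    fixed-dimension embedding vector. (subject_id, window_start) is unique.
    """

    subject_ids: np.ndarray
    window_starts: np.ndarray
    splits: np.ndarray
    diagnoses: np.ndarray
    embeddings: np.ndarray

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        self.splits = np.asarray(self.splits, dtype=object)
        self.diagnoses = np.asarray(self.diagnoses, dtype=object)
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        n = len(self.subject_ids)
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be 2-D (rows x dims)")
        for name, arr in [
            ("window_starts", self.window_starts),
            ("splits", self.splits),
            ("diagnoses", self.diagnoses),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n}")
        if self.embeddings.shape[0] != n:
            raise ValueError("embedding row count mismatch")
        keys = list(zip(self.subject_ids, self.window_starts))
        if len(set(keys)) != n:
            raise ValueError("(subject_id, window_start) pairs must be unique")

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    def mask(self, splits=None, diagnoses=None) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if splits is not None:
            m &= np.isin(self.splits.astype(str), list(splits))
        if diagnoses is not None:
            m &= np.isin(self.diagnoses.astype(str), list(diagnoses))
        return m

    def select(self, splits=None, diagnoses=None) -> "EmbeddingTable":
        m = self.mask(splits=splits, diagnoses=diagnoses)
        return EmbeddingTable(
            self.subject_ids[m],
            self.window_starts[m],
            self.splits[m],
            self.diagnoses[m],
            self.embeddings[m],
        )

    def sorted(self) -> "EmbeddingTable":
        order = np.lexsort((self.window_starts, self.subject_ids.astype(str)))
        return EmbeddingTable(
            self.subject_ids[order],
            self.window_starts[order],
            self.splits[order],
            self.diagnoses[order],
            self.embeddings[order],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_ids.astype(str),
                "window_start": self.window_starts,
                "split": self.splits.astype(str),
                "diagnosis": self.diagnoses.astype(str),
            }
        )
        for j in range(self.dim):
            df[f"z{j}"] = self.embeddings[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EmbeddingTable":
        cols = list(df.columns)
        if tuple(cols[:4]) != EMBEDDING_KEY_COLUMNS:
            raise ValueError(
                f"embedding table must start with columns {EMBEDDING_KEY_COLUMNS}, "
                f"got {cols[:4]}"
            )
        zcols = cols[4:]
        expected = [f"z{j}" for j in range(len(zcols))]
        if zcols != expected:
            raise ValueError(
                f"embedding value columns must be {expected}, got {zcols}"
            )
        emb = df[zcols].to_numpy(dtype=float) if zcols else np.zeros((len(df), 0))
        return cls(
            df["subject_id"].astype(str).to_numpy(dtype=object),
            df["window_start"].to_numpy(dtype=int),
            df["split"].astype(str).to_numpy(dtype=object),
            df["diagnosis"].astype(str).to_numpy(dtype=object),
            emb,
        )


def write_embeddings(table: EmbeddingTable, path) -> None:
    """Write an embedding table as TSV (UTF-8, '.' decimal, lossless floats)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_embeddings(path) -> EmbeddingTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip"
    )
    if df.empty and len(df.columns) >= 4:
        # header-only file: coerce dtypes explicitly
        df = df.astype({"window_start": int}, errors="ignore")
    return EmbeddingTable.from_frame(df)
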