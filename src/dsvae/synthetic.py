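"""Synthetic multivariate timecourses with known slow/fast latent structure.

The generator emulates the generative assumptions behind the windowed
sequence-VAE: each subject carries a slowly drifting "context" factor
(an Ornstein-Uhlenbeck-style random walk whose mean differs between the
patient and control groups) and fast "local" dynamics (an order-1
autoregression), mixed — linearly or through a tanh nonlinearity — into the
observed component channels with additive Gaussian noise.

Because the ground-truth factors are known, downstream stages (training,
window classification, context-recovery scoring, clustering) are testable
without access-restricted clinical data. The generator makes no attempt to
simulate hemodynamics, scanner noise spectra, or head motion.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import h5py
import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import GroupKFold, cross_val_predict

from .io_windows import EmbeddingTable, SubjectRecord, write_timecourses


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    Defaults: two groups of 50 subjects, 10 observed components, 160
    timesteps at a 2 s sampling interval, a 2-dimensional context factor
    whose group mean is offset by a vector of norm 2 for patients, context
    drift timescale of 40 timesteps (80 s), AR(1) local dynamics with
    coefficient 0.6 and unit innovation variance, tanh mixing, and
    observation noise with standard deviation 0.2.
    """

    n_subjects_per_group: int = 50
    n_components: int = 10
    n_timesteps: int = 160
    context_dim: int = 2
    local_dim: int = 4
    context_group_offset: tuple[float, ...] = (2.0, 0.0)
    context_drift_timescale: float = 40.0
    ar_coefficient: float = 0.6
    mixing: str = "tanh"
    noise_std: float = 0.2
    sampling_interval: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects_per_group", "n_components", "n_timesteps",
                     "context_dim", "local_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if len(self.context_group_offset) != self.context_dim:
            raise ValueError(
                f"context_group_offset has length {len(self.context_group_offset)}, "
                f"expected context_dim = {self.context_dim}"
            )
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1 for stationarity")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.context_drift_timescale <= 0:
            raise ValueError("context_drift_timescale must be > 0")
        if self.mixing not in ("linear", "tanh"):
            raise ValueError(f"mixing must be 'linear' or 'tanh', got {self.mixing!r}")


@dataclass
class GroundTruth:
    """Per-subject latent trajectories and group labels.

    ``context[sid]`` is (context_dim, T), slowly varying; ``local[sid]`` is
    (local_dim, T). Stored alongside — never inside — the SubjectRecords.
    """

    context: dict[str, np.ndarray]
    local: dict[str, np.ndarray]
    group: dict[str, str]

    def subject_ids(self) -> list[str]:
        return sorted(self.context)


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based stream: reproducible per subject, independent of order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, index)))


def _ou_path(rng, dim, T, mean, timescale):
    """Stationary OU-style walk: unit marginal variance, lag-1 autocorrelation
    exp(-1/timescale)."""
    rho = np.exp(-1.0 / timescale)
    innov_scale = np.sqrt(1.0 - rho**2)
    x = np.empty((dim, T))
    x[:, 0] = mean + rng.standard_normal(dim)
    eps = rng.standard_normal((dim, T - 1)) if T > 1 else None
    for t in range(1, T):
        x[:, t] = mean + rho * (x[:, t - 1] - mean) + innov_scale * eps[:, t - 1]
    return x


def _ar1_path(rng, dim, T, coeff):
    """AR(1) with unit innovation variance, initialized from its stationary
    distribution (variance 1 / (1 - coeff^2))."""
    x = np.empty((dim, T))
    x[:, 0] = rng.standard_normal(dim) / np.sqrt(1.0 - coeff**2)
    eps = rng.standard_normal((dim, T - 1)) if T > 1 else None
    for t in range(1, T):
        x[:, t] = coeff * x[:, t - 1] + eps[:, t - 1]
    return x


def mixing_matrix(spec: SyntheticSpec) -> np.ndarray:
    """The dataset's fixed mixing matrix: (n_components, context_dim+local_dim)
    Gaussian with unit-norm rows, drawn once from the spec seed."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))
    A = rng.standard_normal((spec.n_components, spec.context_dim + spec.local_dim))
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    return A


def generate_dataset(
    spec: SyntheticSpec,
    mixing_matrix_override: np.ndarray | None = None,
) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate the cohort. Fully deterministic given ``spec.seed``.

    Control subjects' context factor drifts around zero; patients' around
    ``context_group_offset``. Observed data is
    ``mixing(A @ [context; local]) + noise``. Subject metadata (age,
    cognitive score) is drawn from group-dependent normal distributions
    matching published multi-site schizophrenia cohort demographics, and is
    independent of the latent trajectories.

    ``mixing_matrix_override`` substitutes a caller-supplied mixing matrix
    (e.g. identity, for exactness tests).
    """
    A = mixing_matrix(spec) if mixing_matrix_override is None else np.asarray(
        mixing_matrix_override, dtype=float
    )
    if A.shape != (spec.n_components, spec.context_dim + spec.local_dim):
        raise ValueError(
            f"mixing matrix must have shape "
            f"({spec.n_components}, {spec.context_dim + spec.local_dim}), got {A.shape}"
        )
    offset = np.asarray(spec.context_group_offset, dtype=float)
    n_total = 2 * spec.n_subjects_per_group

    records: list[SubjectRecord] = []
    truth = GroundTruth(context={}, local={}, group={})
    for i in range(n_total):
        group = "control" if i < spec.n_subjects_per_group else "patient"
        sid = f"sub-{i:04d}"
        rng = _subject_rng(spec.seed, i)
        mean = offset if group == "patient" else np.zeros(spec.context_dim)
        c = _ou_path(rng, spec.context_dim, spec.n_timesteps, mean,
                     spec.context_drift_timescale)
        l = _ar1_path(rng, spec.local_dim, spec.n_timesteps, spec.ar_coefficient)
        y = A @ np.vstack([c, l])
        if spec.mixing == "tanh":
            y = np.tanh(y)
        if spec.noise_std > 0:
            y = y + spec.noise_std * rng.standard_normal(y.shape)
        else:
            # keep the noise draw out of the stream only when exactly zero
            y = y.copy()
        if group == "patient":
            age = float(np.clip(39.0 + 12.0 * rng.standard_normal(), 18, 65))
            cog = float(-1.6 + 1.2 * rng.standard_normal())
        else:
            age = float(np.clip(37.0 + 11.0 * rng.standard_normal(), 18, 65))
            cog = float(0.0 + 0.9 * rng.standard_normal())
        records.append(
            SubjectRecord(
                subject_id=sid,
                diagnosis=group,
                data=y,
                age=age,
                cognitive_score=cog,
                sampling_interval=spec.sampling_interval,
            )
        )
        truth.context[sid] = c
        truth.local[sid] = l
        truth.group[sid] = group
    return records, truth


# ---------------------------------------------------------------------------
# Ground-truth I/O
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    with h5py.File(path, "w") as f:
        for sid in truth.subject_ids():
            g = f.create_group(sid)
            g.create_dataset("context", data=truth.context[sid])
            g.create_dataset("local", data=truth.local[sid])
            g.attrs["group"] = truth.group[sid]


def read_ground_truth(path) -> GroundTruth:
    truth = GroundTruth(context={}, local={}, group={})
    with h5py.File(path, "r") as f:
        for sid in f.keys():
            truth.context[sid] = np.asarray(f[sid]["context"])
            truth.local[sid] = np.asarray(f[sid]["local"])
            truth.group[sid] = str(f[sid].attrs["group"])
    return truth


def write_dataset(records, truth, out_dir) -> None:
    """Write the cohort in the standard exchange layout: per-subject TSVs +
    metadata.csv + ground_truth.h5."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_timecourses(records, out_dir / "timecourses", out_dir / "metadata.csv")
    write_ground_truth(truth, out_dir / "ground_truth.h5")


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def window_context_targets(
    table: EmbeddingTable, truth: GroundTruth, width: int = 32
) -> np.ndarray:
    """True context target per window: the time-average of the ground-truth
    context trajectory over that window."""
    targets = np.empty((len(table), len(next(iter(truth.context.values())))))
    for r, (sid, start) in enumerate(zip(table.subject_ids, table.window_starts)):
        if sid not in truth.context:
            raise KeyError(f"subject {sid!r} missing from ground truth")
        targets[r] = truth.context[sid][:, start : start + width].mean(axis=1)
    return targets


def context_recovery_score(
    table: EmbeddingTable,
    truth: GroundTruth,
    width: int = 32,
    n_splits: int = 5,
) -> float:
    """R-squared of an affine map from embeddings to window-averaged true
    context factors, fit and evaluated by subject-level cross-validation.

    Predictions are pooled across folds (GroupKFold over subjects) and a
    single uniformly-averaged multi-output R-squared is returned. The score
    is invariant to invertible affine transformations of the embeddings;
    1.0 means perfect recovery, <= 0 means no better than the mean.
    """
    y = window_context_targets(table, truth, width=width)
    X = table.embeddings
    groups = table.subject_ids.astype(str)
    n_groups = len(set(groups))
    if n_groups < 2:
        raise ValueError("need at least 2 subjects for subject-level CV")
    cv = GroupKFold(n_splits=min(n_splits, n_groups))
    pred = cross_val_predict(LinearRegression(), X, y, cv=cv, groups=groups)
    return float(r2_score(y, pred, multioutput="uniform_average"))
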