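"""Two-group synthetic BOLD-like cohort simulator.

Each subject is a stationary first-order vector autoregression

    x_t = A_g x_{t-1} + e_t,      e_t ~ N(0, Sigma_g),

with group-specific lag matrix ``A_g`` (directed, lagged influence — the signal
picked up by Granger causality) and group-specific innovation covariance
``Sigma_g`` (contemporaneous co-fluctuation — the signal picked up by Pearson
correlation and sparse representation).  Groups therefore differ in all three
channels of connectivity information that the downstream estimators target.

Columns are z-scored per subject, so absolute signal units carry no
information, mirroring the scale-free nature of correlation-based networks.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcn import RoiTimeSeries

__all__ = [
    "SimulationConfig",
    "Cohort",
    "default_config",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

_BURN_IN = 200  # VAR burn-in steps discarded before recording


@dataclass
class SimulationConfig:
    """Specification of a two-group VAR(1) cohort.

    ``lag_matrices`` and ``covariances`` hold one n×n matrix per group
    (index 0 = control, 1 = case).  ``affected_rois`` records which ROIs the
    two groups differ on; it is bookkeeping for downstream recovery tests,
    not used by the sampler itself.
    """

    n_subjects_per_group: int = 30
    n_rois: int = 20
    n_timepoints: int = 232
    lag_matrices: tuple[np.ndarray, np.ndarray] = None  # type: ignore[assignment]
    covariances: tuple[np.ndarray, np.ndarray] = None  # type: ignore[assignment]
    noise_sd: float = 1.0
    affected_rois: tuple[int, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be at least 10")
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g, A in enumerate(self.lag_matrices):
            A = np.asarray(A, dtype=float)
            if A.shape != (self.n_rois, self.n_rois):
                raise ValueError(f"group {g} lag matrix has shape {A.shape}, "
                                 f"expected ({self.n_rois}, {self.n_rois})")
            rho = float(np.max(np.abs(np.linalg.eigvals(A))))
            if rho >= 1.0:
                raise ValueError(
                    f"group {g} lag matrix is non-stationary: spectral radius "
                    f"{rho:.4f} >= 1")
        for g, S in enumerate(self.covariances):
            S = np.asarray(S, dtype=float)
            if S.shape != (self.n_rois, self.n_rois):
                raise ValueError(f"group {g} covariance has wrong shape {S.shape}")
            if not np.allclose(S, S.T):
                raise ValueError(f"group {g} covariance is not symmetric")
            if np.min(np.linalg.eigvalsh(S)) <= 0:
                raise ValueError(f"group {g} covariance is not positive definite")


@dataclass
class Cohort:
    """A simulated or loaded two-group collection of ROI time series."""

    subjects: list[RoiTimeSeries]
    labels: np.ndarray  # 1 = case, 0 = control
    manifest: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        shapes = {s.values.shape for s in self.subjects}
        if len(shapes) > 1:
            raise ValueError(f"subject matrices have differing shapes: {shapes}")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1} or len(uniq) != 2:
            raise ValueError(f"labels must contain exactly the two values 0 and 1, got {sorted(uniq)}")
        if self.manifest is None:
            self.manifest = pd.DataFrame({
                "subject_id": [s.subject_id for s in self.subjects],
                "label": self.labels,
                "group": ["case" if l == 1 else "control" for l in self.labels],
            })

    def __len__(self) -> int:
        return len(self.subjects)


def default_config(
    n_subjects_per_group: int = 30,
    n_rois: int = 20,
    n_timepoints: int = 232,
    n_affected: int = 8,
    self_coupling: float = 0.25,
    cov_coupling: tuple[float, float] = (0.05, 0.25),
    lag_coupling: tuple[float, float] = (0.0, 0.3),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SimulationConfig:
    """Build the standard two-group study conditions.

    Control and case groups share diagonal self-memory ``self_coupling``.  The
    first ``n_affected`` ROIs form the affected set, split in half so the two
    kinds of coupling difference live on disjoint ROIs: within the first half
    the case group carries stronger pairwise innovation correlation
    (``cov_coupling[1]`` vs ``cov_coupling[0]``, a contemporaneous/symmetric
    effect), and over the second half it carries a directed influence chain
    ROI k -> ROI k+1 of strength ``lag_coupling[1]`` (vs ``lag_coupling[0]``
    in controls, a lagged/directed effect).  No single estimator sees the
    whole group difference, which is exactly the premise that makes fusing
    complementary connection patterns worthwhile.
    """
    if n_affected > n_rois:
        raise ValueError("n_affected cannot exceed n_rois")
    affected = tuple(range(n_affected))
    cov_set = affected[: n_affected // 2]
    lag_set = affected[n_affected // 2:]
    lags, covs = [], []
    for g in range(2):
        A = np.eye(n_rois) * self_coupling
        for a, b in zip(lag_set, lag_set[1:]):
            A[b, a] += lag_coupling[g]  # row = target, col = source
        S = np.eye(n_rois) * noise_sd**2
        for i in cov_set:
            for j in cov_set:
                if i != j:
                    S[i, j] = cov_coupling[g] * noise_sd**2
        lags.append(A)
        covs.append(S)
    return SimulationConfig(
        n_subjects_per_group=n_subjects_per_group,
        n_rois=n_rois,
        n_timepoints=n_timepoints,
        lag_matrices=(lags[0], lags[1]),
        covariances=(covs[0], covs[1]),
        noise_sd=noise_sd,
        affected_rois=affected,
        seed=seed,
    )


def _simulate_var1(A: np.ndarray, chol: np.ndarray, t: int,
                   rng: np.random.Generator) -> np.ndarray:
    n = A.shape[0]
    total = t + _BURN_IN
    eps = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total, n))
    x[0] = eps[0]
    for step in range(1, total):
        x[step] = A @ x[step - 1] + eps[step]
    return x[_BURN_IN:]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw an independent stationary VAR(1) realisation per subject.

    Deterministic given ``config.seed``: every subject consumes its own
    spawned substream of one root generator, so cohorts are bitwise
    reproducible and individual subjects do not depend on cohort size order.
    Columns are z-scored per subject after a discarded burn-in.
    """
    config.validate()
    chols = [np.linalg.cholesky(np.asarray(S, dtype=float))
             for S in config.covariances]
    lags = [np.asarray(A, dtype=float) for A in config.lag_matrices]

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(2 * config.n_subjects_per_group)
    labels = np.array([0] * config.n_subjects_per_group +
                      [1] * config.n_subjects_per_group)
    roi_labels = [f"ROI{i:03d}" for i in range(config.n_rois)]
    subjects = []
    for idx, (lab, ss) in enumerate(zip(labels, streams)):
        rng = np.random.Generator(np.random.PCG64(ss))
        x = _simulate_var1(lags[lab], chols[lab], config.n_timepoints, rng)
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
        subjects.append(RoiTimeSeries(values=x, roi_labels=roi_labels,
                                      subject_id=f"sub-{idx:04d}"))
    return Cohort(subjects=subjects, labels=labels)


# ---------------------------------------------------------------------------
# on-disk representation: one delimited text file per subject + TSV manifest

def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> str:
    """Write each subject as a t×n TSV (no header) plus a manifest.

    The manifest is a TSV with columns subject_id, label, file.  Floats are
    written with 17 significant digits so the round trip through text is
    bitwise lossless for float64.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for subj, label in zip(cohort.subjects, cohort.labels):
        fname = f"{subj.subject_id}.tsv"
        np.savetxt(os.path.join(directory, fname), subj.values,
                   delimiter="\t", fmt="%.17g",
                   header="\t".join(subj.roi_labels), comments="#")
        rows.append({"subject_id": subj.subject_id, "label": int(label),
                     "file": fname})
    manifest_path = os.path.join(directory, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_cohort(directory: str | os.PathLike) -> Cohort:
    """Load a cohort written by :func:`write_cohort`.

    Rejects manifests whose labels are not binary, missing subject files, and
    subject matrices whose shapes disagree (all offending files are named).
    """
    directory = os.fspath(directory)
    manifest_path = os.path.join(directory, "manifest.tsv")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"no manifest.tsv in {directory}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "label", "file"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest missing columns {sorted(required - set(manifest.columns))}")
    label_values = set(manifest["label"].unique().tolist())
    if not label_values <= {0, 1}:
        raise ValueError(f"manifest labels must be 0/1, found {sorted(label_values)}")

    subjects = []
    shapes: dict[tuple[int, int], list[str]] = {}
    for _, row in manifest.iterrows():
        path = os.path.join(directory, row["file"])
        if not os.path.exists(path):
            raise FileNotFoundError(f"manifest references missing file: {row['file']}")
        with open(path) as fh:
            first = fh.readline()
        roi_labels = None
        if first.startswith("#"):
            roi_labels = first[1:].strip().split("\t")
        values = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
        if roi_labels is None or len(roi_labels) != values.shape[1]:
            roi_labels = [f"ROI{i:03d}" for i in range(values.shape[1])]
        shapes.setdefault(values.shape, []).append(str(row["file"]))
        subjects.append(RoiTimeSeries(values=values, roi_labels=roi_labels,
                                      subject_id=str(row["subject_id"])))
    if len(shapes) > 1:
        detail = "; ".join(f"{shape}: {files}" for shape, files in shapes.items())
        raise ValueError(f"subject matrices have inconsistent shapes — {detail}")
    return Cohort(subjects=subjects, labels=manifest["label"].to_numpy(),
                  manifest=manifest)
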