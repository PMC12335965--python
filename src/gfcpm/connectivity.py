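"""From per-run ROI time series to one general-functional-connectivity matrix.

The processing chain mirrors a standard connectivity pipeline: nuisance
regression (motion, task-evoked responses and their derivatives, optional
CompCor-style components), zero-phase temporal filtering (high-pass for task
runs, band-pass for rest), condition-wise extraction of task frames,
concatenation across conditions and rest, and Pearson correlation with a
Fisher-z transform.  Edge vectors follow a single canonical ordering
(row-major over node pairs i < j, 0-based) used by every other module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic_cohort import TaskDesign

logger = logging.getLogger(__name__)

#: Rotations are converted to arc displacement on a sphere of this radius (mm).
HEAD_RADIUS_MM = 50.0

#: Fisher-z clamp: |r| is capped at 1 - R_CLAMP_EPS before atanh.
R_CLAMP_EPS = 1e-7


class ShapeError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# edge indexing
# ---------------------------------------------------------------------------

def edge_count(n_nodes: int) -> int:
    """Number of undirected edges among ``n_nodes`` nodes: n(n-1)/2."""
    if n_nodes < 2:
        raise ValueError("edge_count requires at least 2 nodes")
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Node index pair (i, j), i < j, for every canonical edge index."""
    return np.triu_indices(n_nodes, 1)


def nodes_to_edge(i: np.ndarray, j: np.ndarray, n_nodes: int) -> np.ndarray:
    """Canonical edge index of node pairs (i < j); vectorized closed form."""
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i >= j) or np.any(i < 0) or np.any(j >= n_nodes):
        raise ValueError("node pairs must satisfy 0 <= i < j < n_nodes")
    return (i * (2 * n_nodes - i - 1)) // 2 + (j - i - 1)


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

def compute_fd(motion: np.ndarray) -> tuple[np.ndarray, float]:
    """Framewise displacement from six rigid-body parameters.

    FD(t) = sum |Delta translation| + 50 mm * sum |Delta rotation(rad)|
    (rotations converted to arc length on a 50-mm sphere); FD(0) = 0 and the
    average includes every frame.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ShapeError(f"motion series must be (time, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ShapeError("need at least 2 frames to compute FD")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.concatenate(
        [[0.0], d[:, :3].sum(axis=1) + HEAD_RADIUS_MM * d[:, 3:].sum(axis=1)]
    )
    return fd, float(fd.mean())


def compcor_components(noise_signals: np.ndarray, n_components: int = 5) -> np.ndarray:
    """CompCor-style nuisance components: top principal components (over time)
    of variance-normalized noise-source signals."""
    X = np.asarray(noise_signals, dtype=float)
    if X.ndim != 2:
        raise ShapeError("noise signals must be (time, sources)")
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    X = X / np.where(sd > 0, sd, 1.0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, U.shape[1])
    return U[:, :k] * S[:k]


# ---------------------------------------------------------------------------
# design regressors
# ---------------------------------------------------------------------------

def _spm_hrf(tr: float) -> np.ndarray:
    from nilearn.glm.first_level import spm_hrf

    return spm_hrf(tr, oversampling=1)


def build_design_regressors(
    design: TaskDesign, tr: float | None = None
) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved boxcar per task condition plus its first difference.

    Columns: one convolved regressor per non-fixation condition in design
    order, followed by the first temporal differences in the same order.
    An all-fixation design yields a (time, 0) array.
    """
    tr = design.tr if tr is None else tr
    conds = design.task_conditions
    T = int(round(design.run_duration / tr))
    if T == 0:
        raise ValueError("empty design")
    hrf = _spm_hrf(tr)
    cols, names = [], []
    for cond in conds:
        box = np.zeros(T)
        for b in design.condition_blocks(cond):
            i0 = int(round(b.onset / tr))
            i1 = min(T, int(round((b.onset + b.duration) / tr)))
            box[i0:i1] = 1.0
        cols.append(np.convolve(box, hrf)[:T])
        names.append(cond)
    for cond, reg in zip(conds, list(cols)):
        cols.append(np.diff(reg, prepend=reg[0]))
        names.append(f"{cond}_derivative")
    X = np.column_stack(cols) if cols else np.empty((T, 0))
    return X, names


@dataclass
class ConfoundSet:
    """Per-run nuisance regressors plus the motion summary.

    ``matrix`` concatenates whatever components are present, in the order
    motion (6) | task regressors + derivatives | CompCor components.
    """

    motion: np.ndarray | None = None
    task_regressors: np.ndarray | None = None
    task_names: list[str] = field(default_factory=list)
    compcor: np.ndarray | None = None
    fd_series: np.ndarray | None = None
    average_fd: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        parts = [
            p for p in (self.motion, self.task_regressors, self.compcor)
            if p is not None and p.size
        ]
        if not parts:
            raise ValueError("ConfoundSet is empty")
        lengths = {p.shape[0] for p in parts}
        if len(lengths) != 1:
            raise ShapeError("confound components disagree on run length")
        return np.column_stack(parts)

    @property
    def names(self) -> list[str]:
        out: list[str] = []
        if self.motion is not None:
            out += ["tx", "ty", "tz", "rx", "ry", "rz"]
        if self.task_regressors is not None:
            out += self.task_names
        if self.compcor is not None:
            out += [f"compcor_{i}" for i in range(self.compcor.shape[1])]
        return out


def build_confounds(
    motion: np.ndarray | None = None,
    design: TaskDesign | None = None,
    noise_signals: np.ndarray | None = None,
    n_compcor: int = 5,
) -> ConfoundSet:
    cs = ConfoundSet()
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        cs.motion = motion
        cs.fd_series, cs.average_fd = compute_fd(motion)
    if design is not None:
        cs.task_regressors, cs.task_names = build_design_regressors(design)
    if noise_signals is not None:
        cs.compcor = compcor_components(noise_signals, n_compcor)
    return cs


# ---------------------------------------------------------------------------
# nuisance regression and filtering
# ---------------------------------------------------------------------------

def regress_confounds(
    ts: np.ndarray, confounds: ConfoundSet | np.ndarray | None
) -> np.ndarray:
    """OLS residuals of each node series on [intercept | confound columns].

    Collinear confound columns are dropped left to right (later duplicates
    lose) with a logged warning, keeping the fit deterministic.
    """
    ts = np.asarray(ts, dtype=float)
    if confounds is None:
        C = np.empty((ts.shape[0], 0))
        names: list[str] = []
    elif isinstance(confounds, ConfoundSet):
        C = confounds.matrix
        names = confounds.names
    else:
        C = np.asarray(confounds, dtype=float)
        names = [f"c{i}" for i in range(C.shape[1])]
    if C.shape[0] != ts.shape[0]:
        raise ShapeError("confound rows must match time-series rows")
    X = np.column_stack([np.ones(ts.shape[0]), C])
    # greedy left-to-right rank filter
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            nm = names[j - 1] if j - 1 < len(names) else f"col{j}"
            logger.warning("dropping collinear confound column %s", nm)
    Xk = X[:, keep]
    beta, *_ = np.linalg.lstsq(Xk, ts, rcond=None)
    return ts - Xk @ beta


def temporal_filter(
    ts: np.ndarray,
    tr: float,
    low_cut: float | None = None,
    high_cut: float | None = None,
) -> np.ndarray:
    """Zero-phase FFT-domain filter with hard cutoffs.

    Keeps frequencies f with ``low_cut <= f <= high_cut`` (an omitted bound is
    open).  A high-pass (``low_cut`` only) removes the DC component, so column
    means are ~0 afterwards.
    """
    ts = np.asarray(ts, dtype=float)
    nyq = 0.5 / tr
    if low_cut is not None and high_cut is not None and not low_cut < high_cut:
        raise ValueError("low_cut must be below high_cut")
    for cut in (low_cut, high_cut):
        if cut is not None and cut > nyq + 1e-12:
            raise ValueError(f"cutoff {cut} Hz exceeds the Nyquist frequency {nyq} Hz")
    if low_cut is None and high_cut is None:
        return ts.copy()
    T = ts.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr)
    mask = np.ones_like(freqs, dtype=bool)
    if low_cut is not None:
        mask &= freqs >= low_cut - 1e-12
    if high_cut is not None:
        mask &= freqs <= high_cut + 1e-12
    spectrum = np.fft.rfft(ts, axis=0)
    spectrum[~mask] = 0.0
    return np.fft.irfft(spectrum, n=T, axis=0)


def extract_condition_segments(
    ts: np.ndarray,
    design: TaskDesign,
    condition: str,
    shift_s: float = 0.0,
) -> np.ndarray:
    """Frames whose acquisition time falls inside a block of ``condition``.

    ``shift_s`` displaces every block window forward (a hemodynamic-onset
    shift), clipped at the run end.  Frames are returned in temporal order.
    """
    ts = np.asarray(ts)
    blocks = design.condition_blocks(condition)
    if not blocks:
        raise ValueError(f"condition {condition!r} absent from design")
    tr = design.tr
    T = ts.shape[0]
    times = np.arange(T) * tr
    sel = np.zeros(T, dtype=bool)
    for b in blocks:
        lo = b.onset + shift_s
        hi = b.onset + b.duration + shift_s
        sel |= (times >= lo - 1e-9) & (times < hi - 1e-9)
    return ts[sel]


# ---------------------------------------------------------------------------
# GFC
# ---------------------------------------------------------------------------

@dataclass
class GFCMatrix:
    """Symmetric Fisher-z connectivity matrix with its canonical edge vector."""

    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = self.matrix
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ShapeError("GFC matrix must be square")
        if not np.allclose(M, M.T, atol=1e-12):
            raise ValueError("GFC matrix must be symmetric")
        if not np.all(np.isfinite(M)):
            raise ValueError("GFC matrix contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def edge_vector(self) -> np.ndarray:
        """Fisher-z values in canonical order (row-major over i < j)."""
        return self.matrix[np.triu_indices(self.n_nodes, 1)]


def build_gfc(segments: list[np.ndarray]) -> GFCMatrix:
    """Concatenate segments and correlate: Pearson r -> Fisher z per node pair.

    |r| is clamped at ``1 - 1e-7`` before atanh; clamped pairs are counted in
    the provenance.  A zero-variance node raises, naming the node.
    """
    if not segments:
        raise ValueError("no segments supplied")
    n_nodes = segments[0].shape[1]
    for seg in segments:
        if seg.shape[1] != n_nodes:
            raise ShapeError("segments disagree on node count")
    X = np.concatenate(segments, axis=0)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 concatenated frames")
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateDataError(f"zero-variance node(s): {dead.tolist()}")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 0.0)
    clamp = 1.0 - R_CLAMP_EPS
    n_clamped = int(np.count_nonzero(np.abs(R) > clamp) // 2)
    if n_clamped:
        logger.warning("%d edge correlation(s) at the clamp ceiling", n_clamped)
    Z = np.arctanh(np.clip(R, -clamp, clamp))
    prov = {
        "n_frames": int(X.shape[0]),
        "n_segments": len(segments),
        "n_clamped_edges": n_clamped,
        "edge_order": "row-major over node pairs i<j, 0-based",
    }
    return GFCMatrix(matrix=Z, provenance=prov)


# ---------------------------------------------------------------------------
# behavior scoring
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        warnings.warn("zero variance; z-scores set to 0", stacklevel=3)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def handwriting_speed_score(
    times_hfc: np.ndarray, times_lfc: np.ndarray
) -> np.ndarray:
    """Handwriting-speed composite: z(1/t_HFC) + z(1/t_LFC) within the cohort.

    Uses the inverse of each copy time so that larger is faster; z-scores use
    the sample SD.  A constant column contributes 0 (with a warning).
    """
    t1 = np.asarray(times_hfc, dtype=float)
    t2 = np.asarray(times_lfc, dtype=float)
    if t1.shape != t2.shape or t1.ndim != 1:
        raise ShapeError("copy-time vectors must be 1-D and equal length")
    if len(t1) < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("copy times must be positive")
    return _zscore(1.0 / t1) + _zscore(1.0 / t2)


# ---------------------------------------------------------------------------
# subject-level pipeline
# ---------------------------------------------------------------------------

#: Task conditions entering the GFC (the drawing control condition is not analyzed).
GFC_CONDITIONS: tuple[str, ...] = ("HFC-copy", "LFC-copy")


def subject_gfc(
    subject,
    task_filter: tuple[float | None, float | None] = (0.008, None),
    rest_filter: tuple[float | None, float | None] = (0.008, 0.09),
    condition_shift_s: float = 0.0,
    conditions: tuple[str, ...] = GFC_CONDITIONS,
) -> GFCMatrix:
    """Run the full per-subject chain on a :class:`SubjectRuns`.

    Task runs: regress motion + task regressors (+ derivatives), then filter
    (default high-pass 0.008 Hz), then extract each copying condition.  Rest:
    regress motion, band-pass 0.008-0.09 Hz.  All segments are concatenated
    and correlated into one Fisher-z matrix.
    """
    segments: list[np.ndarray] = []
    for kind in subject.run_kinds:
        ts = subject.timeseries[kind]
        design = subject.designs.get(kind)
        cs = build_confounds(motion=subject.motion[kind], design=design)
        resid = regress_confounds(ts, cs)
        if design is not None:
            filt = temporal_filter(resid, subject.tr, *task_filter)
            for cond in conditions:
                segments.append(
                    extract_condition_segments(filt, design, cond, condition_shift_s)
                )
        else:
            segments.append(temporal_filter(resid, subject.tr, *rest_filter))
    gfc = build_gfc(segments)
    gfc.provenance.update(
        {
            "subject_id": subject.subject_id,
            "task_filter_hz": list(task_filter),
            "rest_filter_hz": list(rest_filter),
            "conditions": list(conditions),
            "condition_shift_s": condition_shift_s,
        }
    )
    return gfc
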