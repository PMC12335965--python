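"""Synthetic multi-run ROI cohorts with a known ground-truth connectome-behavior link.

The generator emulates the structure of a task + rest fMRI study at the
region-of-interest level: each subject owns a latent correlation matrix
(a group block structure plus subject-specific Fisher-z deviations), BOLD-like
time series are drawn from it for two 318-s task runs and one 480-s resting
run, and a behavioral score is planted on the latent strength of a chosen set
of edges.  Everything downstream (confound regression, connectivity, CPM,
fingerprinting) can therefore be tested against an unambiguous ground truth
without any imaging data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default network labels: 11 named functional networks plus "Unc" (uncertain).
DEFAULT_NETWORKS: tuple[str, ...] = (
    "FPN", "DMN", "SMN", "VAN", "DAN", "AN",
    "VN", "CON", "SCN", "SAN", "Cereb", "Unc",
)

TASK_CONDITIONS: tuple[str, ...] = ("HFC-copy", "LFC-copy", "symbol-draw")
FIXATION = "fixation"

#: Within-trial timing of the copying task (seconds).
TRIAL_FIXATION_S = 0.3
TRIAL_STIMULUS_S = 1.0
TRIAL_RESPONSE_S = 4.7
TRIALS_PER_BLOCK = 5
TASK_BLOCK_S = TRIALS_PER_BLOCK * (TRIAL_FIXATION_S + TRIAL_STIMULUS_S + TRIAL_RESPONSE_S)
FIXATION_BLOCK_S = 12.0
TASK_RUN_S = 318.0
REST_RUN_S = 480.0


class ConfigurationError(ValueError):
    """Invalid generator configuration (sizes, labels, parameter ranges)."""


class GenerationError(RuntimeError):
    """The generator could not produce a valid cohort."""


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParcellationScheme:
    """Node table: contiguous ids, 3-D coordinates and one network label each."""

    node_ids: np.ndarray
    coordinates: np.ndarray
    network_labels: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if n < 2:
            raise ConfigurationError("a parcellation needs at least 2 nodes")
        if not np.array_equal(self.node_ids, np.arange(n)):
            raise ConfigurationError("node ids must be unique and contiguous from 0")
        if self.coordinates.shape != (n, 3):
            raise ConfigurationError("coordinates must be (n_nodes, 3)")
        if len(self.network_labels) != n:
            raise ConfigurationError("every node needs exactly one network label")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def networks(self) -> tuple[str, ...]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.network_labels:
            seen.setdefault(str(lab), None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
                "z": self.coordinates[:, 2],
                "network": self.network_labels,
            }
        )


def make_parcellation(
    n_nodes: int = 264,
    network_sizes: dict[str, int] | None = None,
    seed: int = 0,
) -> ParcellationScheme:
    """Build a parcellation with labels assigned in contiguous blocks.

    Parameters
    ----------
    n_nodes : int
        Number of regions (264 for the default scheme, 200 for a
        Craddock-scale scheme).
    network_sizes : dict, optional
        Mapping label -> node count.  Must sum to ``n_nodes``.  By default the
        nodes are split as evenly as possible over the 12 default labels
        (fewer labels when ``n_nodes`` < 12).
    seed : int
        Seeds the coordinate sampling only; labels are deterministic.
    """
    if n_nodes < 2:
        raise ConfigurationError("n_nodes must be >= 2")
    if network_sizes is None:
        k = min(len(DEFAULT_NETWORKS), n_nodes)
        base, extra = divmod(n_nodes, k)
        network_sizes = {
            lab: base + (1 if i < extra else 0)
            for i, lab in enumerate(DEFAULT_NETWORKS[:k])
        }
    total = sum(network_sizes.values())
    if total != n_nodes:
        bad = max(network_sizes, key=network_sizes.get)  # type: ignore[arg-type]
        raise ConfigurationError(
            f"network sizes sum to {total}, expected {n_nodes} "
            f"(check label {bad!r})"
        )
    labels = np.concatenate(
        [np.repeat(lab, size) for lab, size in network_sizes.items()]
    )
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-70.0, 70.0, size=(n_nodes, 3))
    return ParcellationScheme(
        node_ids=np.arange(n_nodes), coordinates=coords, network_labels=labels
    )


# ---------------------------------------------------------------------------
# task design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    condition: str
    onset: float
    duration: float


@dataclass(frozen=True)
class TaskDesign:
    """Block design of one task run.

    Nine 30-s task blocks (three per condition, five 6-s trials each) with
    four 12-s fixation blocks interspersed; 318 s in total at the defaults.
    """

    tr: float
    blocks: tuple[Block, ...]
    run_duration: float

    def __post_init__(self) -> None:
        t = 0.0
        for b in self.blocks:
            if b.onset < t - 1e-9:
                raise ConfigurationError("blocks overlap or are out of order")
            if abs(round(b.onset / self.tr) * self.tr - b.onset) > 1e-9:
                raise ConfigurationError(
                    f"block onset {b.onset} not on the TR={self.tr} grid"
                )
            t = b.onset + b.duration
        if abs(t - self.run_duration) > 1e-9:
            raise ConfigurationError("blocks do not tile the run duration")

    @property
    def n_frames(self) -> int:
        return int(round(self.run_duration / self.tr))

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for b in self.blocks:
            seen.setdefault(b.condition, None)
        return tuple(seen)

    @property
    def task_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != FIXATION)

    def condition_blocks(self, condition: str) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.condition == condition)

    def tile(self, k: int) -> "TaskDesign":
        """Concatenate ``k`` copies of the design back to back."""
        if k < 1:
            raise ConfigurationError("tile factor must be >= 1")
        blocks = tuple(
            Block(b.condition, b.onset + i * self.run_duration, b.duration)
            for i in range(k)
            for b in self.blocks
        )
        return TaskDesign(self.tr, blocks, self.run_duration * k)


#: Per-trial duration of the copying task (fixation + stimulus + response).
TRIAL_DURATION_S = TRIAL_FIXATION_S + TRIAL_STIMULUS_S + TRIAL_RESPONSE_S


def make_task_design(tr: float = 1.0, order_seed: int | None = None) -> TaskDesign:
    """Build the 318-s copying-task block design.

    The canonical layout alternates a 12-s fixation block with a triplet of
    30-s task blocks (one per condition); ``order_seed`` shuffles the order of
    the nine task blocks while keeping the fixation positions fixed.
    """
    if tr <= 0:
        raise ConfigurationError("TR must be positive")
    for boundary in (FIXATION_BLOCK_S, TASK_BLOCK_S):
        if abs(round(boundary / tr) * tr - boundary) > 1e-9:
            raise ConfigurationError(f"TR={tr} does not divide the {boundary}-s blocks")
    task_seq = [c for c in TASK_CONDITIONS for _ in range(3)]
    if order_seed is not None:
        rng = np.random.default_rng(order_seed)
        task_seq = [task_seq[i] for i in rng.permutation(len(task_seq))]
    else:
        # canonical pseudorandom-looking interleave: H L S / L S H / S H L
        task_seq = [
            TASK_CONDITIONS[(i + j) % 3] for j in range(3) for i in range(3)
        ]
    blocks: list[Block] = []
    t = 0.0
    it = iter(task_seq)
    for chunk in range(4):
        blocks.append(Block(FIXATION, t, FIXATION_BLOCK_S))
        t += FIXATION_BLOCK_S
        if chunk < 3:
            for _ in range(3):
                cond = next(it)
                blocks.append(Block(cond, t, TASK_BLOCK_S))
                t += TASK_BLOCK_S
    return TaskDesign(tr=tr, blocks=tuple(blocks), run_duration=t)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class NoiseParams:
    """Tunable amplitudes of the synthetic data-generating process.

    All time-series amplitudes are in units of the node signal SD (1.0).
    """

    within_r: float = 0.3          #: group-mean correlation inside a network
    between_r: float = 0.05        #: group-mean correlation across networks
    deviation_sd: float = 0.1      #: SD of subject Fisher-z edge deviations
    behavior_noise_sd: float = 0.3  #: noise SD on the latent behavior factor
    drift_amplitude: float = 0.6   #: low-frequency drift added to every node
    task_amplitude: float = 0.5    #: evoked-response amplitude on responsive nodes
    n_task_nodes: int = 30         #: number of task-responsive nodes
    motion_step_sd_mm: float = 0.03     #: random-walk step SD, translations
    motion_step_sd_rad: float = 6e-4    #: random-walk step SD, rotations
    motion_artifact_amplitude: float = 0.3  #: motion-coupled signal amplitude
    reading_behavior_corr: float = 0.5  #: corr(reading score, latent behavior)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would have to estimate."""

    signal_edges: np.ndarray          #: planted edge indices (canonical order)
    edge_signs: np.ndarray            #: +1 positive link, -1 negative link
    effect_size: float                #: target |corr(behavior, latent edge z)|
    realized_effect_sizes: np.ndarray  #: sign-aligned corr(behavior, repaired latent z)
    behavior_noise_sd: float
    latent_edge_z: np.ndarray         #: subjects x edges Fisher z of latent connectomes
    true_scores: np.ndarray           #: latent behavior factor per subject
    task_nodes: np.ndarray            #: task-responsive node indices

    def summary_dict(self) -> dict:
        return {
            "signal_edges": self.signal_edges.tolist(),
            "edge_signs": self.edge_signs.tolist(),
            "effect_size": self.effect_size,
            "realized_effect_sizes": self.realized_effect_sizes.tolist(),
            "behavior_noise_sd": self.behavior_noise_sd,
            "true_scores": self.true_scores.tolist(),
            "task_nodes": self.task_nodes.tolist(),
        }


@dataclass
class SubjectRuns:
    """All runs of one subject: two task runs and one resting run."""

    subject_id: str
    timeseries: dict[str, np.ndarray]  #: run kind -> (time x nodes)
    motion: dict[str, np.ndarray]      #: run kind -> (time x 6)
    designs: dict[str, TaskDesign]     #: task run kind -> design
    tr: float

    def __post_init__(self) -> None:
        for kind, ts in self.timeseries.items():
            if self.motion[kind].shape != (ts.shape[0], 6):
                raise ConfigurationError(
                    f"motion series of run {kind!r} must be (time, 6)"
                )

    @property
    def run_kinds(self) -> tuple[str, ...]:
        return tuple(self.timeseries)


@dataclass
class Cohort:
    subjects: list[SubjectRuns]
    behavior: pd.DataFrame
    covariates: pd.DataFrame
    truth: GroundTruth
    scheme: ParcellationScheme
    task_design: TaskDesign


def _block_correlation(scheme: ParcellationScheme, within: float, between: float) -> np.ndarray:
    lab = scheme.network_labels
    same = lab[:, None] == lab[None, :]
    R = np.where(same, within, between)
    np.fill_diagonal(R, 1.0)
    return R


def repair_correlation(A: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Nearest-correlation repair: clip eigenvalues then rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(A)
    if vals.min() >= eig_floor:
        return A
    vals = np.clip(vals, eig_floor, None)
    A2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(A2))
    A2 = A2 / np.outer(d, d)
    np.fill_diagonal(A2, 1.0)
    if not np.all(np.isfinite(A2)):
        raise GenerationError("correlation repair produced non-finite entries")
    return A2


def _corr_with(columns: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column with ``x`` (across rows)."""
    xc = x - x.mean()
    cc = columns - columns.mean(axis=0)
    denom = np.linalg.norm(cc, axis=0) * np.linalg.norm(xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (cc.T @ xc) / denom


def _hrf_kernel(tr: float) -> np.ndarray:
    from nilearn.glm.first_level import spm_hrf

    return spm_hrf(tr, oversampling=1)


def _evoked_signal(design: TaskDesign, n_frames: int) -> np.ndarray:
    """Summed HRF-convolved boxcar over all task conditions (unit peak boxcar)."""
    tr = design.tr
    box = np.zeros(n_frames)
    for b in design.blocks:
        if b.condition == FIXATION:
            continue
        i0 = int(round(b.onset / tr))
        i1 = min(n_frames, int(round((b.onset + b.duration) / tr)))
        box[i0:i1] = 1.0
    return np.convolve(box, _hrf_kernel(tr))[:n_frames]


def generate_cohort(
    n_subjects: int = 50,
    scheme: ParcellationScheme | None = None,
    n_signal_edges: int = 20,
    effect_size: float = 0.6,
    noise: NoiseParams | None = None,
    seed: int = 0,
    tr: float = 1.0,
    duration_scale: int = 1,
) -> Cohort:
    """Generate a cohort of multi-run time series with a planted brain-behavior link.

    Each subject's latent connectome is the group block-structure matrix plus
    independent Gaussian Fisher-z deviations (SD ``noise.deviation_sd``),
    repaired to a valid correlation matrix by eigenvalue clipping.  A latent
    behavior factor loads on the deviations of ``n_signal_edges`` planted
    edges (half positively, half negatively); the loading is calibrated so
    that the correlation between behavior and the *repaired* latent edge
    strength matches ``effect_size``.  Copy times are exact monotone
    transforms of the behavior factor, so the handwriting-speed composite
    carries the planted effect without extra measurement noise.

    ``duration_scale`` tiles the 318-s task design and extends the rest run by
    the same integer factor; longer runs shrink the sampling noise of the
    empirical connectivity toward the latent ground truth.
    """
    if scheme is None:
        scheme = make_parcellation()
    noise = noise or NoiseParams()
    if not 0.0 <= effect_size < 1.0:
        raise ConfigurationError("effect_size must be in [0, 1)")
    n = scheme.n_nodes
    iu = np.triu_indices(n, 1)
    n_edges = len(iu[0])
    if n_signal_edges > n_edges:
        raise ConfigurationError(
            f"n_signal_edges={n_signal_edges} exceeds the {n_edges} available edges"
        )
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")

    rng = np.random.default_rng(seed)
    R0 = _block_correlation(scheme, noise.within_r, noise.between_r)
    z0 = np.arctanh(R0[iu])

    signal_edges = np.sort(rng.choice(n_edges, size=n_signal_edges, replace=False))
    signs = np.ones(n_signal_edges)
    signs[n_signal_edges // 2:] = -1.0

    g = rng.standard_normal(n_subjects)
    behavior_score = g + noise.behavior_noise_sd * rng.standard_normal(n_subjects)
    c_bg = 1.0 / np.hypot(1.0, noise.behavior_noise_sd)

    xi = rng.standard_normal((n_subjects, n_edges))
    xi_sig = rng.standard_normal((n_subjects, n_signal_edges))

    def build_latents(lam: float) -> tuple[np.ndarray, list[np.ndarray]]:
        dev = noise.deviation_sd * xi
        if n_signal_edges:
            dev[:, signal_edges] = noise.deviation_sd * (
                lam * np.outer(g, signs) + np.sqrt(1.0 - lam**2) * xi_sig
            )
        z = z0[None, :] + dev
        mats = []
        zpost = np.empty_like(z)
        for s in range(n_subjects):
            A = np.eye(n)
            A[iu] = np.tanh(z[s])
            A = A + A.T - np.diag(np.diag(A))
            Ar = repair_correlation(A)
            mats.append(Ar)
            zpost[s] = np.arctanh(np.clip(Ar[iu], -1 + 1e-7, 1 - 1e-7))
        return zpost, mats

    # Calibrate the factor loading so the planted effect survives the
    # positive-definiteness repair (which shrinks and mixes edge deviations).
    lam = 0.0 if effect_size == 0.0 else min(0.999, effect_size / c_bg)
    zpost, mats = build_latents(lam)
    if effect_size > 0.0:
        for _ in range(2):
            realized = np.abs(
                _corr_with(zpost[:, signal_edges], behavior_score) * signs
            ).mean()
            if realized <= 0:
                raise GenerationError("planted effect vanished during repair")
            lam = min(0.999, lam * effect_size / realized)
            zpost, mats = build_latents(lam)
    realized_es = (
        _corr_with(zpost[:, signal_edges], behavior_score) * signs
        if n_signal_edges
        else np.empty(0)
    )

    design = make_task_design(tr).tile(duration_scale)
    rest_frames = int(round(REST_RUN_S * duration_scale / tr))
    task_nodes = np.sort(
        rng.choice(n, size=min(noise.n_task_nodes, n), replace=False)
    )
    evoked = _evoked_signal(design, design.n_frames)

    subjects: list[SubjectRuns] = []
    for s in range(n_subjects):
        L = np.linalg.cholesky(mats[s])
        ts: dict[str, np.ndarray] = {}
        motion: dict[str, np.ndarray] = {}
        designs: dict[str, TaskDesign] = {}
        for kind in ("task-natural", "task-fast", "rest"):
            T = design.n_frames if kind.startswith("task") else rest_frames
            X = rng.standard_normal((T, n)) @ L.T
            # slow drift below the 0.008-Hz high-pass cutoff
            tgrid = np.arange(T) * tr
            freq = rng.uniform(0.002, 0.006)
            phase = rng.uniform(0, 2 * np.pi, size=n)
            X += noise.drift_amplitude * np.sin(
                2 * np.pi * freq * tgrid[:, None] + phase[None, :]
            )
            # motion: smooth random walk, plus a motion-coupled artifact
            steps = rng.standard_normal((T, 6))
            steps[:, :3] *= noise.motion_step_sd_mm
            steps[:, 3:] *= noise.motion_step_sd_rad
            mot = np.cumsum(steps, axis=0)
            mot -= mot[0]
            mot_z = (mot - mot.mean(0)) / np.maximum(mot.std(0), 1e-12)
            W = rng.standard_normal((6, n)) * (noise.motion_artifact_amplitude / np.sqrt(6))
            X += mot_z @ W
            if kind.startswith("task"):
                X[:, task_nodes] += noise.task_amplitude * evoked[:, None]
                designs[kind] = design
            ts[kind] = X
            motion[kind] = mot
        subjects.append(
            SubjectRuns(
                subject_id=f"sub-{s + 1:03d}",
                timeseries=ts,
                motion=motion,
                designs=designs,
                tr=tr,
            )
        )

    # behavioral table: copy times are exact affine-in-inverse transforms of
    # the behavior factor (cohort means/SDs match the adult sample)
    b_std = (behavior_score - behavior_score.mean()) / behavior_score.std(ddof=1)
    inv_hfc = 1.0 / 35.10 + (6.33 / 35.10**2) * b_std
    inv_lfc = 1.0 / 40.09 + (7.75 / 40.09**2) * b_std
    if inv_hfc.min() <= 0 or inv_lfc.min() <= 0:
        raise GenerationError("behavior draw produced non-positive copy speed")
    rho_r = noise.reading_behavior_corr
    reading = 1766.77 + 369.92 * (
        rho_r * b_std + np.sqrt(1 - rho_r**2) * rng.standard_normal(n_subjects)
    )
    age = np.clip(rng.normal(22.36, 2.32, n_subjects), 19, 28)
    sex = (rng.random(n_subjects) < 23 / 50).astype(int)

    from .connectivity import compute_fd

    ids = [s.subject_id for s in subjects]
    motion_summary = np.array(
        [
            sum(compute_fd(s.motion[k])[1] for k in ("task-natural", "task-fast", "rest"))
            for s in subjects
        ]
    )
    behavior = pd.DataFrame(
        {
            "subject_id": ids,
            "copy_time_hfc_s": 1.0 / inv_hfc,
            "copy_time_lfc_s": 1.0 / inv_lfc,
            "reading_score": reading,
        }
    )
    covariates = pd.DataFrame(
        {"subject_id": ids, "age": age, "sex": sex, "motion": motion_summary}
    )
    truth = GroundTruth(
        signal_edges=signal_edges,
        edge_signs=signs,
        effect_size=effect_size,
        realized_effect_sizes=realized_es,
        behavior_noise_sd=noise.behavior_noise_sd,
        latent_edge_z=zpost,
        true_scores=behavior_score,
        task_nodes=task_nodes,
    )
    return Cohort(subjects, behavior, covariates, truth, scheme, design)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort directory layout (delimited text only).

    ``<path>/sub-XXX/<run>.tsv`` (header = node ids), ``motion_<run>.tsv``,
    plus ``behavior.csv``, ``covariates.csv``, ``parcellation.tsv``,
    ``design.json`` and ``ground_truth.json`` at the top level.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = "\t".join(str(i) for i in cohort.scheme.node_ids)
    for subj in cohort.subjects:
        sdir = path / subj.subject_id
        sdir.mkdir(exist_ok=True)
        for kind, ts in subj.timeseries.items():
            np.savetxt(
                sdir / f"{kind}.tsv", ts, delimiter="\t",
                header=header, comments="", fmt="%.6f",
            )
            np.savetxt(
                sdir / f"motion_{kind}.tsv", subj.motion[kind], delimiter="\t",
                header="\t".join(["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"]),
                comments="", fmt="%.8f",
            )
    cohort.behavior.to_csv(path / "behavior.csv", index=False)
    cohort.covariates.to_csv(path / "covariates.csv", index=False)
    cohort.scheme.to_frame().to_csv(path / "parcellation.tsv", sep="\t", index=False)
    design = cohort.task_design
    with open(path / "design.json", "w") as fh:
        json.dump(
            {
                "tr": design.tr,
                "run_duration": design.run_duration,
                "blocks": [
                    {"condition": b.condition, "onset": b.onset, "duration": b.duration}
                    for b in design.blocks
                ],
            },
            fh,
            indent=1,
        )
    with open(path / "ground_truth.json", "w") as fh:
        json.dump(cohort.truth.summary_dict(), fh, indent=1)
    logger.info("wrote cohort of %d subjects to %s", len(cohort.subjects), path)
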