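"""Synthetic glove-like cohorts with planted synergy structure.

The generator emulates the statistical structure the pipeline assumes in real
hand recordings: a small number of latent coordination synergies (fixed
loading vectors over subsets of DoF, perturbed per subject), a set of truly
independent single-DoF channels, smooth band-limited activation signals with
per-task amplitudes, additive measurement noise, and frozen lead-in/lead-out
postures. Because the planted loadings, activations and offsets are returned
alongside the recordings, every pipeline stage can be checked against ground
truth without any downloaded data.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .dof import DOF_LABELS, DOF_NAMES, N_DOF, dof_index
from .errors import ParameterError
from .io import JointAngleRecording, write_recordings

MIN_PLANTED_SEPARATION_DEG = 60.0

# Default planted structure: an MCP-flexion coordination and a PIP-flexion
# coordination (index PIP kept independent), the remaining nine DoF driven by
# their own activation signals. Non-uniform block weights make the true
# inter-joint coefficient ratios distinguishable from 1.
_BLOCKS: dict[str, dict[str, float]] = {
    "mcp_flexion": {"MCP2F": 0.60, "MCP3F": 0.55, "MCP4F": 0.45, "MCP5F": 0.37},
    "pip_flexion": {"PIP3F": 0.65, "PIP4F": 0.55, "PIP5F": 0.52},
}
_INDEPENDENT: tuple[str, ...] = (
    "CMC1F", "CMC1A", "MCP1F", "IP1F", "PIP2F",
    "MCP2-3A", "MCP3-4A", "MCP4-5A", "PalmArch",
)

# Resting offsets (degrees from the flat-hand posture) and activation gains
# (degrees of angular excursion per unit activation SD): flexions get larger
# baselines and excursions than abductions and the palmar arch.
_OFFSETS = {
    "flexion": 20.0, "abduction": 2.0, "arch": 5.0,
}
_INDEP_GAINS = {
    "flexion": 12.0, "abduction": 7.0, "arch": 6.0,
}
_BLOCK_GAINS = {"mcp_flexion": 28.0, "pip_flexion": 26.0}


def _default_loadings() -> np.ndarray:
    cols = []
    for weights in _BLOCKS.values():
        v = np.zeros(N_DOF)
        for name, w in weights.items():
            v[dof_index(name)] = w
        cols.append(v / np.linalg.norm(v))
    return np.stack(cols, axis=1)


def _default_offsets() -> np.ndarray:
    return np.array([_OFFSETS[d.kind] for d in DOF_LABELS])


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 8
    n_tasks: int = 6
    frames_per_task: int = 600
    sample_rate: float = 100.0
    loadings: np.ndarray = field(default_factory=_default_loadings)
    block_gains: tuple = (
        _BLOCK_GAINS["mcp_flexion"],
        _BLOCK_GAINS["pip_flexion"],
    )
    independent: tuple = _INDEPENDENT
    subject_loading_jitter_deg: float = 5.0
    noise_sd_deg: float = 1.0
    static_pad_s: float = 0.5
    activation_cutoff_hz: float = 5.0
    task_amplitude_range: tuple = (0.7, 1.3)
    offsets: np.ndarray = field(default_factory=_default_offsets)
    seed: int = 0

    @property
    def n_blocks(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_latent(self) -> int:
        """Planted dimensionality: coordination blocks + independent channels."""
        return self.n_blocks + len(self.independent)

    def planted_directions(self) -> np.ndarray:
        """All planted loading directions: blocks plus independent unit vectors."""
        cols = [self.loadings[:, j] for j in range(self.n_blocks)]
        for name in self.independent:
            e = np.zeros(N_DOF)
            e[dof_index(name)] = 1.0
            cols.append(e)
        return np.stack(cols, axis=1)

    def validate(self) -> None:
        from .clustering import pc_angle

        if self.n_subjects < 1 or self.n_tasks < 1 or self.frames_per_task < 4:
            raise ParameterError("cohort dimensions too small")
        if self.noise_sd_deg < 0 or self.subject_loading_jitter_deg < 0:
            raise ParameterError("noise and jitter SDs must be >= 0")
        if self.sample_rate <= 2 * self.activation_cutoff_hz:
            raise ParameterError("sample rate must exceed twice the activation cutoff")
        L = self.loadings
        if L.shape[0] != N_DOF or len(self.block_gains) != L.shape[1]:
            raise ParameterError("loadings must be 16 x m with one gain per block")
        block_support = {
            DOF_NAMES[i] for i in np.flatnonzero(np.any(L != 0, axis=1))
        }
        if block_support & set(self.independent):
            raise ParameterError("independent DoF must not appear in a block loading")
        dirs = self.planted_directions()
        for a, b in itertools.combinations(range(dirs.shape[1]), 2):
            ang = pc_angle(dirs[:, a], dirs[:, b])
            if ang < MIN_PLANTED_SEPARATION_DEG - 1e-9:
                raise ParameterError(
                    f"planted loadings {a} and {b} are only {ang:.1f} deg apart "
                    f"(need >= {MIN_PLANTED_SEPARATION_DEG})"
                )


@dataclass
class GroundTruth:
    """Everything needed to check recovery: loadings, activations, true maps."""

    config: SynthConfig
    subject_loadings: dict  # subject_id -> 16 x m jittered block loadings
    activations: dict  # (subject_id, task_id) -> n_latent x frames (pad-free)
    offsets: np.ndarray

    @property
    def n_latent(self) -> int:
        return self.config.n_latent

    def block_of(self, name: str) -> int | None:
        """Index of the coordination block a DoF belongs to, or None."""
        j = dof_index(name)
        hits = np.flatnonzero(self.config.loadings[j, :] != 0)
        return int(hits[0]) if hits.size else None

    def true_affine(self, rep_set) -> tuple[dict, dict]:
        """The exact affine map implied by the planted (unjittered) structure.

        For an estimated DoF d inside coordination block b whose representative
        member is r: angle_d = offset_d + (w_d / w_r) (angle_r - offset_r),
        every other coefficient zero.
        """
        intercepts: dict[str, float] = {}
        coefs: dict[str, dict[str, float]] = {}
        rep_labels = rep_set.labels
        for name in rep_set.estimated_labels:
            b = self.block_of(name)
            c = {r: 0.0 for r in rep_labels}
            if b is None:
                intercepts[name] = float(self.offsets[dof_index(name)])
            else:
                w = self.config.loadings[:, b]
                reps_in_block = [r for r in rep_labels if w[dof_index(r)] != 0]
                if len(reps_in_block) != 1:
                    raise ParameterError(
                        f"block {b} must have exactly one representative member, "
                        f"got {reps_in_block}"
                    )
                r = reps_in_block[0]
                x = w[dof_index(name)] / w[dof_index(r)]
                c[r] = float(x)
                intercepts[name] = float(
                    self.offsets[dof_index(name)] - x * self.offsets[dof_index(r)]
                )
            coefs[name] = c
        return intercepts, coefs

    def save(self, path) -> None:
        data = {
            "loadings": self.config.loadings.tolist(),
            "offsets": self.offsets.tolist(),
            "block_gains": list(self.config.block_gains),
            "independent": list(self.config.independent),
            "subject_loadings": {
                s: L.tolist() for s, L in self.subject_loadings.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def _smooth_activation(rng, n_frames, sample_rate, cutoff_hz) -> np.ndarray:
    """Band-limited unit-SD activation: low-passed white noise."""
    sos = sp_signal.butter(2, cutoff_hz, btype="low", fs=sample_rate, output="sos")
    raw = rng.standard_normal(n_frames + 200)  # burn-in for filter settling
    smooth = sp_signal.sosfiltfilt(sos, raw)[100:-100]
    smooth = smooth - smooth.mean()
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _jitter_loading(rng, w: np.ndarray, jitter_deg: float) -> np.ndarray:
    """Perturb a unit loading by a random angular deviation ~ jitter_deg."""
    if jitter_deg == 0:
        return w.copy()
    scale = np.tan(np.radians(jitter_deg)) / np.sqrt(N_DOF - 1)
    v = w + rng.normal(scale=scale, size=N_DOF)
    return v / np.linalg.norm(v)


def generate_cohort(cfg: SynthConfig) -> tuple[list[JointAngleRecording], GroundTruth]:
    """Generate a full multi-subject, multi-task cohort.

    Angles are ``offsets + blocks + independents + noise`` framed by exact
    static pads (the pad frames repeat the first/last motion frame, so their
    angular velocity is identically zero). The same seed reproduces the cohort
    bit for bit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pad = int(round(cfg.static_pad_s * cfg.sample_rate))
    amp_lo, amp_hi = cfg.task_amplitude_range
    indep_idx = [dof_index(n) for n in cfg.independent]
    indep_gain = np.array([_INDEP_GAINS[DOF_LABELS[i].kind] for i in indep_idx])

    recordings = []
    subject_loadings = {}
    activations = {}
    for s in range(cfg.n_subjects):
        subject_id = f"S{s + 1:02d}"
        L_s = np.stack(
            [
                _jitter_loading(rng, cfg.loadings[:, b], cfg.subject_loading_jitter_deg)
                for b in range(cfg.n_blocks)
            ],
            axis=1,
        )
        subject_loadings[subject_id] = L_s
        for t in range(cfg.n_tasks):
            task_id = f"T{t + 1:02d}"
            acts = np.stack(
                [
                    _smooth_activation(
                        rng, cfg.frames_per_task, cfg.sample_rate, cfg.activation_cutoff_hz
                    )
                    for _ in range(cfg.n_latent)
                ]
            )
            amps = rng.uniform(amp_lo, amp_hi, size=cfg.n_latent)
            acts = acts * amps[:, None]
            activations[(subject_id, task_id)] = acts

            motion = np.tile(cfg.offsets, (cfg.frames_per_task, 1))
            for b in range(cfg.n_blocks):
                motion += cfg.block_gains[b] * np.outer(acts[b], L_s[:, b])
            for k, j in enumerate(indep_idx):
                motion[:, j] += indep_gain[k] * acts[cfg.n_blocks + k]
            if cfg.noise_sd_deg > 0:
                motion += rng.normal(scale=cfg.noise_sd_deg, size=motion.shape)

            if pad > 0:
                angles = np.concatenate(
                    [np.tile(motion[0], (pad, 1)), motion, np.tile(motion[-1], (pad, 1))]
                )
            else:
                angles = motion
            recordings.append(
                JointAngleRecording(subject_id, task_id, angles, cfg.sample_rate)
            )
    truth = GroundTruth(
        config=cfg,
        subject_loadings=subject_loadings,
        activations=activations,
        offsets=cfg.offsets.copy(),
    )
    return recordings, truth


def make_toy_fixture() -> tuple[list[JointAngleRecording], GroundTruth]:
    """Deterministic miniature cohort (2 subjects x 2 tasks x 200 frames)."""
    cfg = SynthConfig(
        n_subjects=2,
        n_tasks=2,
        frames_per_task=160,
        static_pad_s=0.2,
        subject_loading_jitter_deg=2.0,
        noise_sd_deg=0.5,
        seed=20240,
    )
    return generate_cohort(cfg)


def write_cohort(recordings, truth: GroundTruth, data_path, truth_path=None) -> None:
    """Write the cohort CSV plus an optional ground-truth sidecar (JSON)."""
    write_recordings(recordings, data_path)
    if truth_path is not None:
        truth.save(truth_path)
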