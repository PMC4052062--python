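"""Synthetic trajectories and STDDV matrices with known domain structure.

Real domain decompositions come from MD trajectories that are far too
expensive to regenerate, so the package carries a generator that emulates
the *statistical* signature such trajectories leave in the pair-distance
fluctuation matrix: a few internally near-rigid domains moving
quasi-independently (low STDDV inside each block, high between blocks),
optionally plus high-mobility linker atoms mimicking flexible loops.  No
force field is involved — only the block phenomenology of S matters.

Every generator takes an explicit seed and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .exceptions import ParameterError, SemirigidError
from .matrix import STDDVMatrix
from .trajectory import Trajectory

#: Label used for linker atoms in ground-truth label vectors.
LINKER_LABEL = -1


@dataclass
class DomainSpec:
    """Recipe for a synthetic multi-domain trajectory.

    Defaults describe the package's reference study condition: three
    domains of 10 atoms each, 0.01 nm internal jitter (thermal noise well
    below backbone scale), 0.5 nm of quasi-independent inter-domain motion,
    200 frames — a clearly separable but non-trivial instance.

    Attributes
    ----------
    domain_sizes
        Atoms per domain.
    internal_noise_sd
        Per-atom, per-frame isotropic jitter [nm] inside each domain.
    inter_domain_motion_sd
        Amplitude [nm] of each domain's independent rigid motion per frame
        (translation sd per component; rotation angles are scaled so the
        displacement at the domain surface is comparable).
    n_linker_atoms, linker_noise_sd
        Optional freely-jittering atoms emulating flexible loops.
    n_frames, seed
        Trajectory length and RNG seed.
    """

    domain_sizes: tuple[int, ...] = (10, 10, 10)
    internal_noise_sd: float = 0.01
    inter_domain_motion_sd: float = 0.5
    n_linker_atoms: int = 0
    linker_noise_sd: float = 0.3
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.domain_sizes = tuple(int(s) for s in self.domain_sizes)
        if not self.domain_sizes or min(self.domain_sizes) < 1:
            raise ParameterError("domain_sizes must be positive integers")
        if not any(s >= 2 for s in self.domain_sizes):
            raise ParameterError(
                "degenerate spec: at least one domain needs >= 2 atoms"
            )
        if self.n_frames < 2:
            raise ParameterError("n_frames must be at least 2")
        for name in ("internal_noise_sd", "inter_domain_motion_sd",
                     "linker_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if self.n_linker_atoms < 0:
            raise ParameterError("n_linker_atoms must be nonnegative")


#: Spread [nm] of the random point cloud each domain is built from.
_DOMAIN_RADIUS = 0.3
#: Spacing [nm] between consecutive domain centres.
_DOMAIN_SPACING = 2.0


def generate_domain_trajectory(spec: DomainSpec) -> tuple[Trajectory, np.ndarray]:
    """Trajectory of rigid domains in quasi-independent motion.

    Each domain is a fixed random point cloud.  Per frame, each domain is
    rotated by a small random rotation (isotropic axis, angle sd =
    inter_domain_motion_sd / domain radius, so zero motion amplitude means
    no rotation at all) and translated by an i.i.d. normal vector, then
    every atom receives isotropic jitter of ``internal_noise_sd``.  Linker
    atoms jitter independently with ``linker_noise_sd``.  Returns the
    trajectory and ground-truth labels: domain index per atom, with
    linkers marked :data:`LINKER_LABEL`.
    """
    rng = np.random.default_rng(spec.seed)
    n_dom = len(spec.domain_sizes)
    clouds = []
    centers = []
    for d, size in enumerate(spec.domain_sizes):
        center = np.array([d * _DOMAIN_SPACING, 0.0, 0.0])
        clouds.append(rng.normal(0.0, _DOMAIN_RADIUS, (size, 3)))
        centers.append(center)
    linker_base = rng.normal(
        [(n_dom - 1) * _DOMAIN_SPACING / 2.0, 0.0, 0.0],
        _DOMAIN_SPACING / 2.0,
        (spec.n_linker_atoms, 3),
    )
    n_atoms = sum(spec.domain_sizes) + spec.n_linker_atoms
    angle_sd = spec.inter_domain_motion_sd / _DOMAIN_RADIUS
    frames = np.empty((spec.n_frames, n_atoms, 3))
    for t in range(spec.n_frames):
        parts = []
        for cloud, center in zip(clouds, centers):
            rot = Rotation.from_rotvec(rng.normal(0.0, angle_sd, 3))
            shift = rng.normal(0.0, spec.inter_domain_motion_sd, 3)
            parts.append(rot.apply(cloud) + center + shift)
        if spec.n_linker_atoms:
            parts.append(
                linker_base + rng.normal(0.0, spec.linker_noise_sd,
                                         (spec.n_linker_atoms, 3))
            )
        frame = np.concatenate(parts, axis=0)
        frame += rng.normal(0.0, spec.internal_noise_sd, frame.shape)
        frames[t] = frame
    labels = np.concatenate(
        [np.full(s, d) for d, s in enumerate(spec.domain_sizes)]
        + ([np.full(spec.n_linker_atoms, LINKER_LABEL)]
           if spec.n_linker_atoms else [])
    )
    chains = np.concatenate(
        [np.full(s, chr(ord("A") + (d % 20))) for d, s in enumerate(spec.domain_sizes)]
        + ([np.full(spec.n_linker_atoms, "X")] if spec.n_linker_atoms else [])
    )
    meta = pd.DataFrame(
        {
            "atom_name": ["CA"] * n_atoms,
            "res_id": np.arange(1, n_atoms + 1),
            "res_name": ["ALA"] * n_atoms,
            "chain_id": chains,
        }
    )
    return Trajectory(frames, meta), labels


def _as_range(r, name: str) -> tuple[float, float]:
    if np.isscalar(r):
        r = (float(r), float(r))
    lo, hi = float(r[0]), float(r[1])
    if lo < 0 or hi < lo:
        raise ParameterError(f"invalid {name}: ({lo}, {hi})")
    return lo, hi


def generate_block_matrix(
    block_sizes, within_range, between_range, seed: int = 0
) -> tuple[STDDVMatrix, np.ndarray]:
    """Block-structured STDDV matrix with known ground-truth labels.

    Off-diagonal entries inside each diagonal block are drawn uniformly
    from ``within_range``, cross-block entries from ``between_range``
    (scalars allowed for constant values).  With the within range entirely
    below the between range, clustering with n_clust = number of blocks
    recovers the blocks exactly.
    """
    block_sizes = tuple(int(s) for s in block_sizes)
    if not block_sizes or min(block_sizes) < 1:
        raise ParameterError("block_sizes must be positive integers")
    w_lo, w_hi = _as_range(within_range, "within_range")
    b_lo, b_hi = _as_range(between_range, "between_range")
    n = sum(block_sizes)
    if n < 2:
        raise SemirigidError("matrix needs at least 2 atoms")
    labels = np.concatenate([np.full(s, b) for b, s in enumerate(block_sizes)])
    rng = np.random.default_rng(seed)
    values = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    draws = np.where(
        same,
        rng.uniform(w_lo, w_hi, iu[0].size),
        rng.uniform(b_lo, b_hi, iu[0].size),
    )
    values[iu] = draws
    values += values.T
    return STDDVMatrix(values), labels


def generate_random_matrix(
    n_atoms: int, value_range=(0.0, 1.0), seed: int = 0
) -> STDDVMatrix:
    """Structure-free control: i.i.d. uniform pair values, symmetrized."""
    if n_atoms < 2:
        raise ParameterError("n_atoms must be at least 2")
    lo, hi = _as_range(value_range, "value_range")
    rng = np.random.default_rng(seed)
    values = np.zeros((n_atoms, n_atoms))
    iu = np.triu_indices(n_atoms, k=1)
    values[iu] = rng.uniform(lo, hi, iu[0].size)
    values += values.T
    return STDDVMatrix(values)


def worked_example_matrix() -> STDDVMatrix:
    """The 3-atom matrix (S_12 = 0.1, S_13 = S_23 = 1.0) used in examples.

    Its unique 2-cluster ground state is {atoms 0, 1}, {atom 2} with
    q = 0.2 (ordered-pair convention), within-cluster mean 0.1 and
    between-cluster mean 1.0.
    """
    return STDDVMatrix(np.array([
        [0.0, 0.1, 1.0],
        [0.1, 0.0, 1.0],
        [1.0, 1.0, 0.0],
    ]))
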