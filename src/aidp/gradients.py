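"""Diffusion gradient tables (b-values and unit directions), FSL dialect I/O."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Free-water (body temperature) diffusivity, mm^2/s.
D_WATER = 3.0e-3

#: Unit-norm tolerance for nonzero-b directions.
_UNIT_TOL = 1e-4

#: Protocol expectations: at least this many diffusion directions / b0 volumes.
PROTOCOL_MIN_DIRECTIONS = 30
PROTOCOL_MIN_B0 = 5


class GradientTableError(ValueError):
    """Raised for malformed or inconsistent gradient tables."""


@dataclass(frozen=True)
class GradientTable:
    """Acquisition scheme: per-volume b-value (s/mm^2) and gradient direction.

    Directions for b > 0 entries must be unit norm; b = 0 entries may carry a
    zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientTableError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise GradientTableError(
                f"length mismatch: {bvals.shape[0]} b-values vs "
                f"{bvecs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise GradientTableError("negative b-values")
        nz = bvals > 0
        if np.any(nz):
            norms = np.linalg.norm(bvecs[nz], axis=1)
            if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
                raise GradientTableError(
                    "nonzero-b directions must be unit norm within 1e-4"
                )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b0_mask))

    @property
    def n_directions(self) -> int:
        return int(np.sum(~self.b0_mask))

    def validate_protocol(self) -> list[str]:
        """Return warnings for deviations from the acquisition protocol."""
        msgs = []
        if self.n_directions < PROTOCOL_MIN_DIRECTIONS:
            msgs.append(
                f"only {self.n_directions} diffusion directions "
                f"(protocol expects >= {PROTOCOL_MIN_DIRECTIONS})"
            )
        if self.n_b0 < PROTOCOL_MIN_B0:
            msgs.append(
                f"only {self.n_b0} b=0 volumes (protocol expects >= {PROTOCOL_MIN_B0})"
            )
        return msgs


def read_gradient_table(
    bval_path: str | Path,
    bvec_path: str | Path,
    *,
    column_dialect: bool = False,
    warn: bool = True,
) -> GradientTable:
    """Read FSL-style ``.bval`` (1 x n) and ``.bvec`` (3 x n) text files.

    ``column_dialect=True`` accepts an n x 3 bvec layout instead. Directions
    with b > 0 are renormalized to unit length; protocol deviations emit
    ``UserWarning`` unless ``warn=False``.
    """
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, -1) if not column_dialect else bvecs.reshape(-1, 3)
    if not column_dialect:
        if bvecs.shape[0] != 3:
            raise GradientTableError(
                f"FSL bvec file must have 3 rows, got shape {bvecs.shape}"
            )
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.shape[0]:
        raise GradientTableError(
            f"bval has {bvals.shape[0]} entries but bvec has {bvecs.shape[0]}"
        )
    nz = bvals > 0
    norms = np.linalg.norm(bvecs[nz], axis=1)
    if np.any(norms == 0):
        raise GradientTableError("zero-length direction for a nonzero b-value")
    bvecs = bvecs.copy()
    bvecs[nz] /= norms[:, None]
    table = GradientTable(bvals=bvals, bvecs=bvecs)
    if warn:
        for msg in table.validate_protocol():
            warnings.warn(msg, UserWarning, stacklevel=2)
    return table


def write_gradient_table(
    table: GradientTable, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write FSL dialect: a 1 x n ``.bval`` row and a 3 x n ``.bvec`` matrix."""
    np.savetxt(bval_path, table.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, table.bvecs.T, fmt="%.8f")


def make_scheme(
    n_directions: int = 30,
    n_b0: int = 5,
    b_value: float = 1000.0,
    seed: int = 0,
) -> GradientTable:
    """Build a single-shell scheme with roughly uniform directions.

    Directions are drawn on the sphere via a seeded Fibonacci-like spiral so
    the scheme is deterministic and well spread.
    """
    if n_directions < 6:
        raise GradientTableError("need at least 6 diffusion directions")
    idx = np.arange(n_directions, dtype=float)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (idx + 0.5) / n_directions
    theta = 2 * np.pi * idx / golden
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # seeded rotation so distinct seeds give distinct (but equally uniform) sets
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    dirs = dirs @ q.T
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b_value)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)
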