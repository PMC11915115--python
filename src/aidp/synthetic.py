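"""Synthetic cohorts, ROI atlases, ground-truth parameter maps, and DWI signal.

Everything downstream (fitting, feature extraction, classification,
statistics) is exercised on data from this module; all generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from aidp._rng import substream
from aidp.gradients import D_WATER, GradientTable

DIAGNOSES = ("PD", "MSA", "PSP")

# Per-class demographics: mean/SD pairs for the prospective and retrospective
# cohorts (age in years, duration in years since parkinsonism diagnosis,
# severity scales in raw score units).
PROSPECTIVE_AGE = {"PD": (66.6, 7.9), "MSA": (66.1, 9.4), "PSP": (69.9, 6.0)}
RETROSPECTIVE_AGE = {"PD": (63.3, 8.9), "MSA": (66.9, 8.7), "PSP": (70.5, 6.9)}
DURATION = {"PD": (6.3, 1.4), "MSA": (2.0, 2.3), "PSP": (1.9, 1.8)}
UPDRS3 = {"PD": (22.0, 10.3), "MSA": (40.1, 15.3), "PSP": (39.8, 14.9)}
UMSARS = {"PD": (19.1, 7.4), "MSA": (46.9, 16.8), "PSP": (44.7, 14.8)}
PSPRS = {"PD": (10.5, 5.0), "MSA": (28.5, 12.4), "PSP": (40.4, 13.7)}
SEX_MALE_FRACTION = {"PD": 0.62, "MSA": 0.57, "PSP": 0.64}

AGE_RANGE = (40.0, 80.0)  # eligibility window


class AtlasCapacityError(ValueError):
    """Grid too small to host the requested number of regions."""


@dataclass(frozen=True)
class CohortSpec:
    """Counts and distribution parameters for a simulated cohort."""

    n_prospective: dict[str, int] = field(
        default_factory=lambda: {"PD": 99, "MSA": 53, "PSP": 97}
    )
    n_retrospective: dict[str, int] = field(
        default_factory=lambda: {"PD": 211, "MSA": 98, "PSP": 87}
    )
    site_ids: tuple[str, ...] = tuple(f"site{i:02d}" for i in range(1, 22))
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PROSPECTIVE_AGE)
    )
    retro_age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(RETROSPECTIVE_AGE)
    )
    sex_ratio: dict[str, float] = field(
        default_factory=lambda: dict(SEX_MALE_FRACTION)
    )
    duration_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DURATION)
    )
    severity_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "updrs3": dict(UPDRS3),
            "umsars": dict(UMSARS),
            "psprs": dict(PSPRS),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for counts in (self.n_prospective, self.n_retrospective):
            for dx, n in counts.items():
                if dx not in DIAGNOSES:
                    raise ValueError(f"unknown diagnosis {dx!r}")
                if n < 0:
                    raise ValueError(f"negative count for {dx}")
        for dx, frac in self.sex_ratio.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"sex_ratio for {dx} outside [0, 1]")
        for params in (self.age_params, self.retro_age_params, self.duration_params):
            for dx, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {dx}")
        for scale in self.severity_params.values():
            for dx, (_, sd) in scale.items():
                if sd < 0:
                    raise ValueError(f"negative severity SD for {dx}")


@dataclass
class SubjectRecord:
    """One simulated subject; retrospective records carry NA severity fields."""

    subject_id: str
    site: str
    cohort: str  # "prospective" | "retrospective"
    diagnosis: str
    age: float
    sex: str  # "male" | "female"
    duration: float | None
    updrs3: float | None
    umsars: float | None
    psprs: float | None
    pathology: str | None = None
    sessions: int = 1


def _truncated_normal(rng, mean, sd, low, high, size):
    """Draw N(mean, sd) truncated to [low, high] by resampling."""
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate subject records with exact class counts.

    Ages are truncated to the 40-80 year eligibility window, severity scores
    to nonnegative values. Sites are assigned round-robin after a seeded
    shuffle of the subject order, so every site is populated as evenly as the
    counts allow. Prospective subjects carry two scan sessions (test-retest);
    retrospective subjects carry one and have NA duration/UMSARS/PSP-RS.
    """
    rng = substream(spec.seed, "cohort")
    records: list[SubjectRecord] = []
    uid = 0
    for cohort, counts, age_params in (
        ("prospective", spec.n_prospective, spec.age_params),
        ("retrospective", spec.n_retrospective, spec.retro_age_params),
    ):
        for dx in DIAGNOSES:
            n = counts.get(dx, 0)
            if n == 0:
                continue
            ages = _truncated_normal(rng, *age_params[dx], *AGE_RANGE, n)
            male = rng.random(n) < spec.sex_ratio[dx]
            durations = _truncated_normal(rng, *spec.duration_params[dx], 0, 60, n)
            scores = {
                scale: _truncated_normal(rng, *params[dx], 0, 200, n)
                for scale, params in spec.severity_params.items()
            }
            for i in range(n):
                prospective = cohort == "prospective"
                records.append(
                    SubjectRecord(
                        subject_id=f"sub-{uid:04d}",
                        site="",
                        cohort=cohort,
                        diagnosis=dx,
                        age=float(round(ages[i], 1)),
                        sex="male" if male[i] else "female",
                        duration=float(round(durations[i], 1)) if prospective else None,
                        updrs3=float(round(scores["updrs3"][i], 1)),
                        umsars=float(round(scores["umsars"][i], 1)) if prospective else None,
                        psprs=float(round(scores["psprs"][i], 1)) if prospective else None,
                        sessions=2 if prospective else 1,
                    )
                )
                uid += 1
    order = rng.permutation(len(records))
    for pos, idx in enumerate(order):
        records[idx].site = spec.site_ids[pos % len(spec.site_ids)]
    return records


def cohort_to_dataframe(records: list[SubjectRecord]) -> pd.DataFrame:
    """One row per subject; NA fields become empty on CSV export."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "site": [r.site for r in records],
            "cohort": [r.cohort for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "duration": [r.duration for r in records],
            "updrs3": [r.updrs3 for r in records],
            "umsars": [r.umsars for r in records],
            "psprs": [r.psprs for r in records],
            "pathology": [r.pathology for r in records],
            "sessions": [r.sessions for r in records],
        }
    )


def generate_atlas(
    grid_shape: tuple[int, int, int],
    n_regions: int = 132,
    seed: int = 0,
    min_voxels_per_region: int = 8,
) -> np.ndarray:
    """Partition the grid interior into ``n_regions`` labels 1..n_regions.

    A one-voxel background border (label 0) surrounds the brain. Interior
    voxels are split into near-equal runs of a raster scan, then labels are
    shuffled with the seed so region geometry varies between seeds while the
    label set stays 1..n_regions.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 3 for s in grid_shape):
        raise AtlasCapacityError(f"grid {grid_shape} has no interior")
    interior = tuple(s - 2 for s in grid_shape)
    n_interior = int(np.prod(interior))
    if n_interior < n_regions * min_voxels_per_region:
        raise AtlasCapacityError(
            f"grid {grid_shape} has {n_interior} interior voxels; "
            f"{n_regions} regions need >= {n_regions * min_voxels_per_region}"
        )
    rng = substream(seed, "atlas")
    # contiguous raster runs -> spatially coherent slabs of near-equal size
    run_labels = np.repeat(
        np.arange(n_regions), np.diff(np.linspace(0, n_interior, n_regions + 1).astype(int))
    )
    label_map = 1 + rng.permutation(n_regions)
    inner = label_map[run_labels].reshape(interior)
    atlas = np.zeros(grid_shape, dtype=np.int32)
    atlas[1:-1, 1:-1, 1:-1] = inner
    return atlas


@dataclass
class GroundTruthMaps:
    """Per-voxel free-water fraction, tissue tensor, baseline signal, labels."""

    fw_true: np.ndarray  # (X, Y, Z) in [0, 1]
    tensor_true: np.ndarray  # (X, Y, Z, 3, 3), symmetric PSD, mm^2/s
    s0: np.ndarray  # (X, Y, Z), nonnegative
    atlas: np.ndarray  # (X, Y, Z) int, 0 = background

    def __post_init__(self) -> None:
        shapes = {self.fw_true.shape, self.s0.shape, self.atlas.shape,
                  self.tensor_true.shape[:3]}
        if len(shapes) != 1:
            raise ValueError("ground-truth field shapes disagree")
        if np.any(self.fw_true < 0) or np.any(self.fw_true > 1):
            raise ValueError("fw_true outside [0, 1]")
        if np.any(self.s0 < 0):
            raise ValueError("negative s0")

    def copy(self) -> "GroundTruthMaps":
        return GroundTruthMaps(
            self.fw_true.copy(), self.tensor_true.copy(),
            self.s0.copy(), self.atlas.copy(),
        )


def axially_symmetric_tensor(
    fa: float | np.ndarray, md: float | np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Tensor(s) with given FA, mean diffusivity, and principal direction.

    With eigenvalues (md*(1+2a), md*(1-a), md*(1-a)) the closed form
    a = FA / sqrt(3 - 2 FA^2) hits the requested FA exactly.
    """
    fa = np.asarray(fa, dtype=float)
    md = np.asarray(md, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction, axis=-1, keepdims=True)
    a = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam_par = md * (1 + 2 * a)
    lam_perp = md * (1 - a)
    eye = np.eye(3)
    outer = direction[..., :, None] * direction[..., None, :]
    return (
        lam_perp[..., None, None] * eye
        + (lam_par - lam_perp)[..., None, None] * outer
    )


def generate_ground_truth(
    atlas: np.ndarray,
    seed: int = 0,
    fw_base: float = 0.15,
    fa_base: float = 0.45,
    md_base: float = 0.7e-3,
    s0_base: float = 500.0,
    regional_jitter: float = 0.02,
) -> GroundTruthMaps:
    """Baseline (disease-free) parameter maps over an atlas.

    Each region gets its own principal fiber direction and small seeded
    offsets of FW/FA around the global baselines, so regional features carry
    benign between-region structure even before effects are planted.
    """
    rng = substream(seed, "ground-truth")
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    fw = np.zeros(atlas.shape)
    fa = np.zeros(atlas.shape)
    direction = np.zeros(atlas.shape + (3,))
    for lab in labels:
        sel = atlas == lab
        fw[sel] = np.clip(fw_base + rng.normal(0, regional_jitter), 0.0, 1.0)
        fa[sel] = np.clip(fa_base + rng.normal(0, regional_jitter), 0.01, 0.95)
        d = rng.standard_normal(3)
        direction[sel] = d / np.linalg.norm(d)
    inside = atlas > 0
    tensors = np.zeros(atlas.shape + (3, 3))
    tensors[inside] = axially_symmetric_tensor(
        fa[inside], np.full(inside.sum(), md_base), direction[inside]
    )
    s0 = np.where(inside, s0_base, 0.0)
    return GroundTruthMaps(fw_true=fw, tensor_true=tensors, s0=s0, atlas=atlas)


@dataclass(frozen=True)
class EffectSpec:
    """Disease effects on regional FW/FAt plus site and session nuisance terms.

    ``effects`` maps diagnosis -> {region_id: (delta_fw, delta_fat)}. FW
    shifts are additive and clipped to [0, 1]; FAt shifts are realized by
    rebuilding the tensor at the shifted FA (clipped to [0, 1)) with mean
    diffusivity and principal direction preserved.
    """

    effects: dict[str, dict[int, tuple[float, float]]] = field(default_factory=dict)
    site_shift_sd: float = 0.0  # additive FW shift per site
    retest_jitter_sd: float = 0.0  # session-2 FW jitter per subject

    def scaled(self, factor: float) -> "EffectSpec":
        """Same topography with all FW/FAt deltas multiplied by ``factor``."""
        return replace(
            self,
            effects={
                dx: {r: (dfw * factor, dfat * factor) for r, (dfw, dfat) in regs.items()}
                for dx, regs in self.effects.items()
            },
        )


def default_effect_spec(
    n_regions: int = 132, strength: float = 1.0, seed: int = 0
) -> EffectSpec:
    """Disease-specific regional effect topography.

    The study does not disclose which regions drive discrimination, so
    exemplar motor/cerebellar/brainstem-like assignments are invented: each
    diagnosis elevates FW and depresses FAt in its own block of regions.
    """
    rng = substream(seed, "effect-topography")
    labels = rng.permutation(np.arange(1, n_regions + 1))
    k = max(2, n_regions // 8)
    blocks = {"PD": labels[:k], "MSA": labels[k : 2 * k], "PSP": labels[2 * k : 3 * k]}
    effects = {
        dx: {int(r): (0.15 * strength, -0.10 * strength) for r in regs}
        for dx, regs in blocks.items()
    }
    return EffectSpec(effects=effects)


def _fa_md_direction(tensors: np.ndarray):
    """Eigen-decompose a (n, 3, 3) tensor stack into FA, MD, principal axis."""
    vals, vecs = np.linalg.eigh(tensors)
    md = vals.mean(axis=-1)
    num = np.sqrt(((vals - md[..., None]) ** 2).sum(-1))
    den = np.sqrt((vals**2).sum(-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    return np.clip(fa, 0, 1), md, vecs[..., :, -1]


def plant_effects(
    truth: GroundTruthMaps,
    effect: EffectSpec,
    diagnosis: str,
    site_index: int = 0,
    session: int = 1,
    seed: int = 0,
) -> GroundTruthMaps:
    """Apply the diagnosis's regional FW/FAt shifts plus nuisance terms.

    Voxels outside the named regions are untouched unless site/session
    nuisance SDs are nonzero (those apply brain-wide). An empty spec is the
    identity.
    """
    regions = effect.effects.get(diagnosis, {})
    present = set(np.unique(truth.atlas).tolist())
    missing = [r for r in regions if r not in present]
    if missing:
        raise ValueError(f"effect regions not in atlas: {missing}")
    out = truth.copy()
    for region_id, (dfw, dfat) in regions.items():
        sel = truth.atlas == region_id
        out.fw_true[sel] = np.clip(out.fw_true[sel] + dfw, 0.0, 1.0)
        if dfat != 0.0:
            fa, md, pdir = _fa_md_direction(out.tensor_true[sel])
            fa_new = np.clip(fa + dfat, 0.0, 0.9999)
            out.tensor_true[sel] = axially_symmetric_tensor(fa_new, md, pdir)
    if effect.site_shift_sd > 0:
        shift = substream(seed, f"site-shift-{site_index}").normal(
            0, effect.site_shift_sd
        )
        inside = out.atlas > 0
        out.fw_true[inside] = np.clip(out.fw_true[inside] + shift, 0, 1)
    if session > 1 and effect.retest_jitter_sd > 0:
        jitter = substream(seed, f"retest-{session}").normal(
            0, effect.retest_jitter_sd, size=out.fw_true.shape
        )
        inside = out.atlas > 0
        out.fw_true[inside] = np.clip(out.fw_true[inside] + jitter[inside], 0, 1)
    return out


def forward_signal(
    truth: GroundTruthMaps, grad: GradientTable, d_water: float = D_WATER
) -> np.ndarray:
    """Noiseless two-compartment signal, one 3D volume per gradient row.

    S(b, g) = s0 * [(1 - fw) exp(-b g^T D g) + fw exp(-b d_water)].
    """
    b = grad.bvals  # (n,)
    g = grad.bvecs  # (n, 3)
    # quadratic form g^T D g for every voxel x gradient
    quad = np.einsum("ni,xyzij,nj->xyzn", g, truth.tensor_true, g)
    tissue = np.exp(-b[None, None, None, :] * quad)
    water = np.exp(-b * d_water)[None, None, None, :]
    fw = truth.fw_true[..., None]
    return truth.s0[..., None] * ((1.0 - fw) * tissue + fw * water)


def synthesize_dwi(
    truth: GroundTruthMaps,
    grad: GradientTable,
    sigma: float = 0.0,
    seed: int = 0,
    d_water: float = D_WATER,
    noise_model: str = "rician",
) -> np.ndarray:
    """Forward signal with Rician (default) or Gaussian noise of scale sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signal = forward_signal(truth, grad, d_water)
    if sigma == 0:
        return signal
    rng = substream(seed, "dwi-noise")
    if noise_model == "rician":
        n1 = rng.normal(0, sigma, signal.shape)
        n2 = rng.normal(0, sigma, signal.shape)
        return np.sqrt((signal + n1) ** 2 + n2**2)
    if noise_model == "gaussian":
        return signal + rng.normal(0, sigma, signal.shape)
    raise ValueError(f"unknown noise model {noise_model!r}")
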