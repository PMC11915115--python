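"""Quality control, brain masking, and ROI feature extraction.

The classifier input is 2 features per atlas region (regional mean FW and
FAt) plus age and sex: 266 features for the standard 132-region atlas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from aidp.gradients import GradientTable

N_REGIONS_DEFAULT = 132

#: QC pass threshold on the b0 signal-to-noise ratio.
SNR_THRESHOLD_DEFAULT = 5.0

#: Brain-mask threshold as a fraction of the robust (99th percentile) maximum.
MASK_FRACTION_DEFAULT = 0.2


class FeatureError(ValueError):
    """Raised for extraction preconditions (missing regions, bad shapes)."""


@dataclass(frozen=True)
class QCReport:
    snr_b0: float
    pass_qc: bool
    fraction_converged: float = 1.0


@dataclass(frozen=True)
class FeatureVector:
    """Ordered imaging + demographic features with parallel names."""

    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.feature_names):
            raise FeatureError("values/names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FeatureError("feature names must be unique")


def compute_snr(
    dwi: np.ndarray,
    grad: GradientTable,
    mask: np.ndarray,
    threshold: float = SNR_THRESHOLD_DEFAULT,
    fraction_converged: float = 1.0,
) -> QCReport:
    """b0 SNR: mean over masked voxels of (mean b0) / (SD across b0 repeats).

    Needs at least 2 b0 volumes. Noiseless repeats (zero SD) report the
    +infinity sentinel and pass.
    """
    if grad.n_b0 < 2:
        raise FeatureError("SNR needs >= 2 b=0 volumes")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise FeatureError("empty mask")
    b0 = np.asarray(dwi, dtype=float)[..., grad.b0_mask][mask]  # (V, n_b0)
    mean_b0 = b0.mean(axis=1)
    sd_b0 = b0.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd_b0 > 0, mean_b0 / sd_b0, np.inf)
    snr = float(np.mean(ratio))
    return QCReport(
        snr_b0=snr, pass_qc=bool(snr >= threshold),
        fraction_converged=fraction_converged,
    )


def brain_mask(
    dwi: np.ndarray,
    grad: GradientTable,
    fraction: float = MASK_FRACTION_DEFAULT,
) -> np.ndarray:
    """Threshold the mean b0 at ``fraction`` of its robust maximum, keep the
    largest connected component."""
    if grad.n_b0 < 1:
        raise FeatureError("masking needs >= 1 b=0 volume")
    mean_b0 = np.asarray(dwi, dtype=float)[..., grad.b0_mask].mean(axis=-1)
    robust_max = float(np.percentile(mean_b0, 99))
    if robust_max <= 0:
        raise FeatureError("all-zero b0 volume")
    raw = mean_b0 > fraction * robust_max
    labeled, n_comp = ndimage.label(raw)
    if n_comp == 0:
        raise FeatureError("no suprathreshold voxels")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n_comp + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def extract_roi_features(
    fw_map: np.ndarray,
    fat_map: np.ndarray,
    atlas: np.ndarray,
    age: float,
    sex: str,
    n_regions: int = N_REGIONS_DEFAULT,
) -> FeatureVector:
    """Regional mean FW and FAt per atlas label, then age and sex.

    Layout: [fw_r001, fat_r001, fw_r002, fat_r002, ..., age, sex] with sex
    encoded 0 = female, 1 = male. Every label 1..n_regions must be nonempty.
    """
    fw_map = np.asarray(fw_map, dtype=float)
    fat_map = np.asarray(fat_map, dtype=float)
    atlas = np.asarray(atlas)
    if not (fw_map.shape == fat_map.shape == atlas.shape):
        raise FeatureError("maps and atlas must share one grid")
    labels = np.arange(1, n_regions + 1)
    counts = np.bincount(atlas.ravel(), minlength=n_regions + 1)[1 : n_regions + 1]
    missing = labels[counts == 0]
    if missing.size:
        raise FeatureError(f"empty atlas regions: {missing.tolist()}")
    fw_sums = ndimage.sum_labels(fw_map, atlas, labels)
    fat_sums = ndimage.sum_labels(fat_map, atlas, labels)
    fw_means = fw_sums / counts
    fat_means = fat_sums / counts
    if sex not in ("male", "female"):
        raise FeatureError(f"sex must be 'male' or 'female', got {sex!r}")
    values = np.empty(2 * n_regions + 2)
    values[0 : 2 * n_regions : 2] = fw_means
    values[1 : 2 * n_regions : 2] = fat_means
    values[-2] = float(age)
    values[-1] = 1.0 if sex == "male" else 0.0
    names = []
    for r in labels:
        names.append(f"fw_r{r:03d}")
        names.append(f"fat_r{r:03d}")
    names += ["age", "sex"]
    return FeatureVector(values=values, feature_names=tuple(names))


def normalize_to_standard_space(volume: np.ndarray) -> np.ndarray:
    """Interface seam for template normalization.

    Synthetic maps are generated directly in atlas space, so this is the
    identity; a real-data deployment would register to a template here.
    """
    return volume
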