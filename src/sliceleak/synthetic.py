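"""Synthetic labelled 3D cohorts with controllable intra-subject slice correlation.

The generator emulates the statistical structure that makes slice-level
cross-validation leak: each subject owns one 3D volume whose axial slices
are strongly correlated with one another (they are cuts through the same
smooth random field), while volumes of different subjects are independent.
A class label may add a localized intensity shift (``effect_size``), or the
labels may be fully randomized to build a null cohort in which the images
carry no information about the label at all — the synthetic analogue of
relabelling a real cohort with coin flips.

Each subject volume is::

    voxels = template + effect_size * 1[label == 1] * 1[effect_region] + noise

where ``template`` is Gaussian-filtered white noise standardized to mean 0 /
SD 1 inside the brain mask, and ``noise`` is voxelwise i.i.d. Gaussian with
SD ``slice_noise_sd``, drawn independently for every slice.  Because the
template is shared by all slices of a subject and smooth along the
slice axis, within-subject slice pairs correlate strongly while
between-subject pairs do not; ``slice_noise_sd`` is the single knob that
attenuates that correlation.  Intensities outside the mask are exactly
zero, as in skull-stripped scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, InputError

__all__ = [
    "SyntheticConfig",
    "VolumeRecord",
    "ellipsoid_mask",
    "generate_cohort",
    "randomize_labels",
]


Region = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_subjects_per_class:
        Subjects per class; the cohort holds twice this many volumes with
        balanced labels (before any randomization).
    volume_shape:
        ``(n_slices, height, width)`` of every volume, in voxels.
    template_smoothness:
        SD (voxels) of the isotropic Gaussian kernel applied to white noise
        to produce each subject's template; sets the spatial correlation
        length, i.e. how anatomy-like and how slice-to-slice correlated the
        volume is.
    slice_noise_sd:
        SD of the per-slice additive Gaussian noise, on the scale of the
        template (whose in-mask SD is 1).  Values below 1 keep
        within-subject slice correlation above between-subject correlation.
    effect_size:
        Amplitude of the additive intensity shift applied to class-1
        subjects inside ``effect_region``; 0 means no class signal.
    effect_region:
        Axis-aligned half-open sub-box ``((z0, z1), (y0, y1), (x0, x1))``
        where the class shift applies; ``None`` defaults to the central
        half of the volume along every axis.
    randomize_labels:
        Replace the balanced labels by random labels carrying no image
        information (the randomized-label null construction).
    label_randomization:
        How random labels are drawn when ``randomize_labels`` is set:
        ``"coin_flip"`` (independent fair coins, the default) or
        ``"balanced_permutation"`` (a random shuffle of the exactly
        balanced label vector).  At small cohort sizes coin flips leave a
        sizeable class imbalance that a classifier can exploit through its
        prior, which confounds the chance-level reading of the control;
        the balanced permutation removes that confound while keeping
        labels independent of the images.
    seed:
        Seed for all randomness; identical configs generate bit-identical
        cohorts.
    """

    n_subjects_per_class: int = 17
    volume_shape: tuple[int, int, int] = (12, 64, 64)
    template_smoothness: float = 3.0
    slice_noise_sd: float = 0.2
    effect_size: float = 0.0
    effect_region: Optional[Region] = None
    randomize_labels: bool = False
    label_randomization: str = "coin_flip"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label_randomization not in ("coin_flip", "balanced_permutation"):
            raise ConfigurationError(
                f"unknown label_randomization {self.label_randomization!r}"
            )
        if self.n_subjects_per_class <= 0:
            raise ConfigurationError("n_subjects_per_class must be positive")
        if len(self.volume_shape) != 3 or any(int(d) <= 0 for d in self.volume_shape):
            raise ConfigurationError(
                f"volume_shape must be three positive integers, got {self.volume_shape!r}"
            )
        if self.template_smoothness <= 0:
            raise ConfigurationError("template_smoothness must be positive")
        if self.slice_noise_sd < 0:
            raise ConfigurationError("slice_noise_sd must be nonnegative")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be nonnegative")
        if self.effect_region is not None:
            region = self.effect_region
            if len(region) != 3:
                raise ConfigurationError("effect_region needs one (lo, hi) pair per axis")
            for (lo, hi), dim in zip(region, self.volume_shape):
                if not (0 <= lo < hi <= dim):
                    raise ConfigurationError(
                        f"effect_region {region!r} outside volume bounds {self.volume_shape!r}"
                    )

    def resolved_effect_region(self) -> Region:
        if self.effect_region is not None:
            return self.effect_region
        return tuple((dim // 4, dim - dim // 4) for dim in self.volume_shape)  # type: ignore[return-value]


@dataclass
class VolumeRecord:
    """One subject's preprocessed 3D volume.

    ``voxels`` is the ``(n_slices, height, width)`` intensity array (axial
    slice axis first), ``mask`` the boolean brain mask of the same shape.
    """

    subject_id: str
    label: int
    voxels: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.voxels.ndim != 3:
            raise InputError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if self.voxels.shape != self.mask.shape:
            raise InputError(
                f"voxels shape {self.voxels.shape} != mask shape {self.mask.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise InputError(f"subject {self.subject_id!r} has non-finite voxels")
        if self.label not in (0, 1):
            raise InputError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


def ellipsoid_mask(shape: tuple[int, int, int], mid_fill: float = 0.6) -> np.ndarray:
    """Centered ellipsoidal brain mask.

    The mid-axial cross-section covers ``mid_fill`` of the slice area; the
    polar semi-axis slightly exceeds the half-depth of the volume so every
    slice keeps a non-empty elliptical cross-section.  The shrinking
    cross-section towards the poles gives slices a foreground-area
    gradient, which is what makes entropy-based slice ranking informative.
    """
    nz, ny, nx = shape
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    az = (nz - 1) / 2.0 + max(1.0, 0.1 * nz)  # poles stay inside the ellipsoid
    r = np.sqrt(mid_fill / np.pi)  # ellipse with axes r*ny, r*nx fills mid_fill
    ay, ax = max(r * ny, 1.0), max(r * nx, 1.0)
    z, y, x = np.ogrid[:nz, :ny, :nx]
    return (
        ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2
    ) <= 1.0


def _subject_template(
    shape: tuple[int, int, int], smoothness: float, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    field3d = gaussian_filter(rng.standard_normal(shape), sigma=smoothness, mode="reflect")
    inside = field3d[mask]
    field3d = (field3d - inside.mean()) / inside.std()
    field3d[~mask] = 0.0
    return field3d


def generate_cohort(config: SyntheticConfig) -> list[VolumeRecord]:
    """Generate a balanced, labelled cohort of synthetic volumes.

    Returns ``2 * n_subjects_per_class`` records.  Labels are balanced by
    construction; when ``config.randomize_labels`` is set they are then
    replaced by independent fair coin flips (images untouched), so that
    label and image are statistically independent whenever
    ``effect_size == 0``.
    """
    rng = np.random.default_rng(config.seed)
    mask = ellipsoid_mask(config.volume_shape)
    (z0, z1), (y0, y1), (x0, x1) = config.resolved_effect_region()
    effect = np.zeros(config.volume_shape)
    effect[z0:z1, y0:y1, x0:x1] = config.effect_size

    n_total = 2 * config.n_subjects_per_class
    records: list[VolumeRecord] = []
    for i in range(n_total):
        label = i % 2  # alternate so subject order carries no class block structure
        template = _subject_template(
            config.volume_shape, config.template_smoothness, mask, rng
        )
        voxels = template.copy()
        if label == 1 and config.effect_size > 0:
            voxels += effect
        if config.slice_noise_sd > 0:
            voxels += config.slice_noise_sd * rng.standard_normal(config.volume_shape)
        voxels[~mask] = 0.0
        records.append(
            VolumeRecord(
                subject_id=f"sub-{i:03d}", label=label, voxels=voxels, mask=mask.copy()
            )
        )

    if config.randomize_labels:
        records = randomize_labels(
            records, seed=config.seed + 1, method=config.label_randomization
        )
    return records


def randomize_labels(
    cohort: Sequence[VolumeRecord], seed: int, method: str = "coin_flip"
) -> list[VolumeRecord]:
    """Replace every label by a random one; images untouched.

    This is the randomized-label control: after relabelling, no classifier
    can genuinely beat chance under subject-level evaluation, so any
    above-chance test accuracy measures leakage in the evaluation scheme
    rather than signal in the data.  ``method="coin_flip"`` draws
    independent fair coins; ``method="balanced_permutation"`` shuffles an
    exactly balanced label vector, removing the class-prior imbalance that
    coin flips leave in small cohorts.
    """
    if len(cohort) == 0:
        raise InputError("cannot randomize labels of an empty cohort")
    rng = np.random.default_rng(seed)
    if method == "coin_flip":
        new_labels = rng.integers(0, 2, size=len(cohort))
    elif method == "balanced_permutation":
        n = len(cohort)
        new_labels = np.array([0] * (n - n // 2) + [1] * (n // 2))
        rng.shuffle(new_labels)
    else:
        raise ConfigurationError(f"unknown label randomization method {method!r}")
    return [
        VolumeRecord(
            subject_id=rec.subject_id,
            label=int(lab),
            voxels=rec.voxels,
            mask=rec.mask,
        )
        for rec, lab in zip(cohort, new_labels)
    ]
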