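"""Synthetic multi-sequence 3D phantom cohorts with partial annotation.

The generator emulates the statistical structure of a screening-style
bi-parametric MRI cohort: a majority of lesion-negative cases, a minority of
positive cases of which only a fraction carry released expert masks, and the
remainder are known positive from pathology reports but unannotated
("withheld").  Each case has three co-registered channels that mimic the
qualitative contrast of T2-weighted, ADC and high-b diffusion imaging:
lesions depress the ADC-like channel and elevate the DWI-like channel by
``contrast * noise_sd``, so a single scalar controls task difficulty
relative to the additive noise floor.

Sampling recipe (fully deterministic given ``seed``)
----------------------------------------------------
Cohort-level stream ``default_rng([seed, 0])`` draws, in order:

1. the positive case indices: ``sorted(choice(n_cases, n_pos, replace=False))``
   with ``n_pos = rint(prevalence * n_cases)`` (ties to even);
2. the human-annotated subset of those:
   ``sorted(choice(positives, n_human, replace=False))`` with
   ``n_human = rint(human_label_fraction * n_pos)``.

Per-case stream ``default_rng([seed, 1000 + case_index])`` draws, in order:

1. one smooth background texture field per channel (standard-normal field,
   Gaussian-filtered at sigma = 3 voxels, renormalized to unit SD);
2. if the case is positive: the lesion count ``integers(lo, hi + 1)``, then
   per lesion a center (uniform direction x cube-root-uniform radius inside
   0.75 of the organ ellipsoid) followed by three per-axis radii
   ``uniform(r_lo, r_hi)`` in mm;
3. one iid Gaussian noise field per channel (SD = ``noise_sd``).

Ground-truth lesions are the 26-connected components of the union of the
seeded ellipsoids (ellipsoids that touch merge into one lesion, as any
component-based detector would see them), labeled 1..K in decreasing-volume
order, so the labels partition the lesion support.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import gaussian_filter

STATUSES = ("human", "pseudo", "withheld_positive", "negative")
STRATEGIES = ("supervised", "semi_supervised", "fully_supervised")

# channel order is fixed package-wide: (T2w-like, ADC-like, DWI-like)
CHANNELS = ("t2w", "adc", "dwi")

_BASE_IN = {"t2w": 1.0, "adc": 1.0, "dwi": 0.3}
_BASE_OUT = {"t2w": 0.2, "adc": 0.3, "dwi": 0.1}
# lesion offset per channel, in units of contrast * noise_sd
_LESION_EFFECT = {"t2w": -0.5, "adc": -1.0, "dwi": +1.0}
_TEXTURE_SIGMA = 3.0  # voxels


def round_half_even(x: float) -> int:
    """Banker's rounding used for all deterministic count rules."""
    return int(np.rint(x))


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the partially annotated screening regime: ~30% of cases
    positive, half of the positives human-annotated, 1-3 small lesions per
    positive case.
    """

    n_cases: int = 40
    grid_shape: tuple = (32, 48, 48)
    voxel_spacing: tuple = (1.0, 1.0, 1.0)  # mm, (z, y, x)
    prevalence: float = 0.3
    human_label_fraction: float = 0.5
    lesions_per_positive: tuple = (1, 3)
    lesion_radius_range: tuple = (2.0, 5.0)  # mm
    contrast: float = 3.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if len(self.grid_shape) != 3 or any(s < 2 for s in self.grid_shape):
            raise ValueError("grid_shape must be three voxel counts >= 2")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive mm values")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if not 0.0 <= self.human_label_fraction <= 1.0:
            raise ValueError("human_label_fraction must be in [0, 1]")
        lo, hi = self.lesions_per_positive
        if not (1 <= lo <= hi <= 3):
            raise ValueError("lesions_per_positive must be an integer range within [1, 3]")
        r_lo, r_hi = self.lesion_radius_range
        if not 0 < r_lo <= r_hi:
            raise ValueError("lesion_radius_range must satisfy 0 < lo <= hi")
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        # the smallest lesion must fit inside the organ region of the grid
        for ax in range(3):
            diameter_vox = 2.0 * r_lo / self.voxel_spacing[ax]
            if diameter_vox + 2 > self.grid_shape[ax]:
                raise ValueError(
                    f"grid too small to place smallest lesion: axis {ax} has "
                    f"{self.grid_shape[ax]} voxels but the minimum lesion "
                    f"diameter is {diameter_vox:.1f} voxels"
                )

    @property
    def n_positive(self) -> int:
        return round_half_even(self.prevalence * self.n_cases)

    @property
    def n_human(self) -> int:
        return round_half_even(self.human_label_fraction * self.n_positive)


@dataclass
class AnnotatedCase:
    """One subject: channels, optional released mask, annotation provenance."""

    case_id: str
    channels: np.ndarray  # (3, z, y, x) float32, order (t2w, adc, dwi)
    gt_mask: np.ndarray | None  # (z, y, x) int16, one positive label per lesion
    case_positive: bool
    annotation_status: str
    voxel_spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.annotation_status not in STATUSES:
            raise ValueError(f"unknown annotation_status {self.annotation_status!r}")
        if (self.annotation_status == "negative") != (not self.case_positive):
            raise ValueError("annotation_status 'negative' must match case_positive=False")
        if not self.case_positive and self.gt_mask is not None and self.gt_mask.any():
            raise ValueError("negative case must have an all-background mask")

    @property
    def grid_shape(self) -> tuple:
        return self.channels.shape[1:]

    @property
    def n_lesions(self) -> int:
        if self.gt_mask is None:
            return 0
        return int(self.gt_mask.max())


@dataclass
class Cohort:
    """A generated cohort: released cases, truth manifest, hidden masks.

    ``hidden_masks`` holds the true masks of withheld positives so that the
    fully supervised view can reveal them; the released cases never expose
    them.
    """

    cases: list
    manifest: pd.DataFrame
    config: PhantomConfig
    hidden_masks: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.cases)

    def __len__(self):
        return len(self.cases)

    def true_mask(self, case_id: str) -> np.ndarray:
        """The ground-truth mask regardless of release status."""
        case = next(c for c in self.cases if c.case_id == case_id)
        if case.case_id in self.hidden_masks:
            return self.hidden_masks[case.case_id]
        if case.gt_mask is None:
            raise KeyError(f"no mask known for {case_id}")
        return case.gt_mask


def _organ_mask(grid_shape, semiaxes, center) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in grid_shape],
                             indexing="ij")
    r2 = (((zz - center[0]) / semiaxes[0]) ** 2
          + ((yy - center[1]) / semiaxes[1]) ** 2
          + ((xx - center[2]) / semiaxes[2]) ** 2)
    return r2 <= 1.0


def _ellipsoid_mask(grid_shape, center, radii_vox) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in grid_shape],
                             indexing="ij")
    r2 = (((zz - center[0]) / radii_vox[0]) ** 2
          + ((yy - center[1]) / radii_vox[1]) ** 2
          + ((xx - center[2]) / radii_vox[2]) ** 2)
    m = r2 <= 1.0
    # guarantee at least the voxel nearest the center
    idx = tuple(int(np.clip(round(c), 0, n - 1)) for c, n in zip(center, grid_shape))
    m[idx] = True
    return m


def _sample_lesions(rng, config: PhantomConfig, organ_center, organ_semiaxes):
    """Draw lesion supports for one positive case; see module docstring for order."""
    lo, hi = config.lesions_per_positive
    k = int(rng.integers(lo, hi + 1))
    masks = []
    for _ in range(k):
        direction = rng.standard_normal(3)
        direction /= max(np.linalg.norm(direction), 1e-12)
        radius_frac = rng.uniform() ** (1.0 / 3.0)
        center = organ_center + direction * radius_frac * 0.75 * np.asarray(organ_semiaxes)
        radii_mm = rng.uniform(*config.lesion_radius_range, size=3)
        radii_vox = radii_mm / np.asarray(config.voxel_spacing)
        masks.append(_ellipsoid_mask(config.grid_shape, center, radii_vox))
    return masks


def _label_lesions(masks) -> np.ndarray:
    """Label the lesion support; labels partition it in decreasing-volume order.

    Seeded ellipsoids that touch or overlap merge into a single lesion: a
    ground-truth lesion is a 26-connected component of the union support, as
    a detector post-processing connected components would see it.  Labels
    are assigned 1..K by decreasing component volume (ties by first voxel in
    scan order).
    """
    if not masks:
        return None
    support = np.logical_or.reduce(masks)
    comp, n = ndimage.label(support, structure=np.ones((3, 3, 3), dtype=bool))
    sizes = [(int((comp == lab).sum()), lab) for lab in range(1, n + 1)]
    sizes.sort(key=lambda t: (-t[0], t[1]))
    label_map = np.zeros(support.shape, dtype=np.int16)
    for new_lab, (_, old_lab) in enumerate(sizes, start=1):
        label_map[comp == old_lab] = new_lab
    return label_map


def generate_case(config: PhantomConfig, case_index: int, positive: bool) -> tuple:
    """Generate one case's channels and true lesion label map."""
    rng = np.random.default_rng([config.seed, 1000 + case_index])
    shape = config.grid_shape
    center = (np.asarray(shape) - 1) / 2.0
    semiaxes = 0.40 * np.asarray(shape)
    organ = _organ_mask(shape, semiaxes, center)

    textures = {}
    for ch in CHANNELS:
        t = rng.standard_normal(shape)
        t = gaussian_filter(t, _TEXTURE_SIGMA)
        t /= max(t.std(), 1e-12)
        textures[ch] = t

    if positive:
        lesion_masks = _sample_lesions(rng, config, center, semiaxes)
        label_map = _label_lesions(lesion_masks)
        lesion_support = label_map > 0
    else:
        label_map = np.zeros(shape, dtype=np.int16)
        lesion_support = np.zeros(shape, dtype=bool)

    amp = config.contrast * config.noise_sd
    channels = []
    for ch in CHANNELS:
        vol = np.where(organ, _BASE_IN[ch], _BASE_OUT[ch]).astype(np.float64)
        vol += 0.5 * config.noise_sd * textures[ch]
        vol[lesion_support] += _LESION_EFFECT[ch] * amp
        vol += rng.normal(0.0, config.noise_sd, size=shape)
        channels.append(vol)
    return np.stack(channels).astype(np.float32), label_map


def generate_cohort(config: PhantomConfig) -> Cohort:
    """Generate a deterministic cohort with the configured annotation regime.

    Exactly ``rint(prevalence * n_cases)`` cases are positive; of those,
    ``rint(human_label_fraction * n_pos)`` release their masks with status
    ``human`` and the rest are ``withheld_positive`` (case-level positivity
    known, mask hidden).  Negative cases release an all-background mask.
    """
    cohort_rng = np.random.default_rng([config.seed, 0])
    n_pos = config.n_positive
    positives = set()
    if n_pos > 0:
        positives = set(
            int(i) for i in sorted(cohort_rng.choice(config.n_cases, size=n_pos,
                                                     replace=False))
        )
    human = set()
    if n_pos > 0 and config.n_human > 0:
        pos_sorted = np.array(sorted(positives))
        human = set(
            int(i) for i in sorted(cohort_rng.choice(pos_sorted, size=config.n_human,
                                                     replace=False))
        )

    voxel_mm3 = float(np.prod(config.voxel_spacing))
    cases, rows, hidden = [], [], {}
    for idx in range(config.n_cases):
        positive = idx in positives
        case_id = f"case_{idx:04d}"
        channels, label_map = generate_case(config, idx, positive)
        if positive:
            status = "human" if idx in human else "withheld_positive"
        else:
            status = "negative"
        released = label_map
        if status == "withheld_positive":
            hidden[case_id] = label_map
            released = None
        cases.append(AnnotatedCase(case_id=case_id, channels=channels,
                                   gt_mask=released, case_positive=positive,
                                   annotation_status=status,
                                   voxel_spacing=tuple(config.voxel_spacing)))
        n_lesions = int(label_map.max())
        volumes = [
            float((label_map == lab).sum()) * voxel_mm3 for lab in range(1, n_lesions + 1)
        ]
        rows.append({
            "case_id": case_id,
            "status": status,
            "case_positive": int(positive),
            "n_lesions": n_lesions,
            "lesion_volumes_mm3": ";".join(f"{v:.2f}" for v in volumes),
        })
    manifest = pd.DataFrame(rows)
    return Cohort(cases=cases, manifest=manifest, config=config, hidden_masks=hidden)


def split_by_strategy(cohort: Cohort, strategy: str) -> list:
    """Assemble a training-set view for one of the three supervision strategies.

    * ``supervised``: human-annotated positives plus all negatives; withheld
      positives are excluded entirely.
    * ``semi_supervised``: the supervised set plus the withheld positives,
      still mask-less — they are slots for pseudo-labeling and contribute
      only the consistency term until pseudo-labeled.
    * ``fully_supervised``: every positive with its true mask revealed, plus
      all negatives.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    view = []
    for case in cohort.cases:
        if case.annotation_status == "withheld_positive":
            if strategy == "supervised":
                continue
            if strategy == "semi_supervised":
                view.append(case)
            else:
                view.append(dataclasses.replace(
                    case, gt_mask=cohort.hidden_masks[case.case_id],
                    annotation_status="human"))
        else:
            view.append(case)
    return view
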