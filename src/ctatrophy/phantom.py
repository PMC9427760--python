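"""Synthetic skull-stripped brain-CT phantoms with ground-truth labels.

The phantom is a nested-ellipsoid brain model: an outer sulcal-CSF
shell, a gray-matter rind, a white-matter core, and a two-lobed central
ventricle whose mid-ventricular axial slice shows the classic
"butterfly" shape.  Atrophy is modeled by two dials that mirror what a
radiologist grades:

* ``ventricle_scale`` — uniform volumetric enlargement of the ventricle
  lobes (ex-vacuo dilation accompanying medial-temporal atrophy);
* ``cortical_thinning`` — the fraction of gray-matter voxels converted,
  outermost first, into sulcal CSF (sulcal widening with cortical
  atrophy).

``simulate_cohort`` draws per-region atrophy severities, maps them to
ordinal visual-rating scores (FA/PA on 0-3, MTA on 0-4) with optional
+/-1-step rating noise, and couples them to the phantom geometry so the
downstream features carry a recoverable severity signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imgio import (
    CTVolume,
    LabelVolume,
    LABEL_BACKGROUND,
    LABEL_CSF,
    LABEL_GM,
    LABEL_WM,
)
from .grading import REGIONS, REGION_SCALE_MAX, RatingRecord, binarize_vrs

__all__ = ["PhantomParams", "PhantomSubject", "generate_phantom", "simulate_cohort"]

#: Default mean tissue intensities, HU-like.  CT shows GM brighter than WM.
DEFAULT_TISSUE_MEANS = {"CSF": 8.0, "GM": 38.0, "WM": 28.0}

_TISSUE_LABEL = {"CSF": LABEL_CSF, "GM": LABEL_GM, "WM": LABEL_WM}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters for one phantom subject.

    ``gm_thickness`` is the gray-matter rind thickness in normalized
    ellipsoid-radius units; it varies across real people, so the cohort
    simulator jitters it per subject.
    """

    grid_shape: tuple[int, int, int] = (24, 48, 48)
    ventricle_scale: float = 1.0
    cortical_thinning: float = 0.0
    noise_sd: float = 0.0
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    seed: int = 0
    gm_thickness: float = 0.18
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 3.3)

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(d) < 16 for d in self.grid_shape):
            raise ValueError(f"grid_shape components must each be >= 16, got {self.grid_shape}")
        if self.ventricle_scale < 0:
            raise ValueError("ventricle_scale must be non-negative")
        if not 0.0 <= self.cortical_thinning <= 1.0:
            raise ValueError("cortical_thinning must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if set(self.tissue_means) != {"CSF", "GM", "WM"}:
            raise ValueError("tissue_means must have exactly the keys {CSF, GM, WM}")
        tm = self.tissue_means
        if not tm["CSF"] < tm["WM"] < tm["GM"]:
            raise ValueError(
                "CT contrast ordering violated: need CSF mean < WM mean < GM mean, "
                f"got {tm}"
            )
        if not 0.05 <= self.gm_thickness <= 0.5:
            raise ValueError("gm_thickness must be in [0.05, 0.5]")


@dataclass
class PhantomSubject:
    """One simulated subject: CT, ground-truth labels, and ratings."""

    ct: CTVolume
    labels: LabelVolume
    ventricle_mask: np.ndarray
    true_severity: dict[str, float] | None = None
    ratings: list[RatingRecord] | None = None
    subject_id: str = "phantom"
    params: PhantomParams | None = None

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels.data != LABEL_BACKGROUND


def _normalized_radius(shape: tuple[int, int, int], semi_frac: float = 0.46) -> tuple:
    """Normalized ellipsoid radius field and the grid center / semi-axes."""
    center = [(d - 1) / 2.0 for d in shape]
    semi = [semi_frac * d for d in shape]
    zz, yy, xx = np.meshgrid(*(np.arange(d, dtype=np.float64) for d in shape), indexing="ij")
    r = np.sqrt(
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    return r, center, semi


def generate_phantom(params: PhantomParams) -> PhantomSubject:
    """Generate one phantom subject; deterministic for a fixed seed.

    Raises ``ValueError`` if the grid is too small for all compartments
    (any tissue class or the ventricle would be empty).
    """
    shape = tuple(int(d) for d in params.grid_shape)
    r, center, semi = _normalized_radius(shape)

    csf_shell = 0.08
    r_gm_out = 1.0 - csf_shell
    r_wm_out = r_gm_out - params.gm_thickness

    labels = np.full(shape, LABEL_BACKGROUND, dtype=np.int16)
    brain = r <= 1.0
    labels[brain] = LABEL_CSF                 # sulcal shell by default
    labels[r <= r_gm_out] = LABEL_GM
    labels[r <= r_wm_out] = LABEL_WM

    # Two mirrored ventricle lobes, elongated anterior-posterior, offset
    # left/right of the midline so a mid-ventricular axial slice shows a
    # butterfly.  Lobe axes scale with ventricle_scale**(1/3) per axis so
    # the lobe volume scales (approximately) linearly with the dial.
    s = params.ventricle_scale ** (1.0 / 3.0)
    lobe_semi = (0.30 * semi[0] * s, 0.28 * semi[1] * s, 0.11 * semi[2] * s)
    zz, yy, xx = np.meshgrid(*(np.arange(d, dtype=np.float64) for d in shape), indexing="ij")
    ventricle = np.zeros(shape, dtype=bool)
    for sign in (-1.0, 1.0):
        cx = center[2] + sign * 0.20 * semi[2]
        lobe = (
            ((zz - center[0]) / lobe_semi[0]) ** 2
            + ((yy - center[1]) / lobe_semi[1]) ** 2
            + ((xx - cx) / lobe_semi[2]) ** 2
        ) <= 1.0
        ventricle |= lobe
    ventricle &= r <= r_wm_out  # keep strictly interior to the WM core
    labels[ventricle] = LABEL_CSF

    # Cortical thinning: convert the outermost fraction of GM voxels to
    # sulcal CSF (deterministic: sorted by radius, ties by flat index).
    if params.cortical_thinning > 0:
        gm_flat = np.flatnonzero(labels.ravel() == LABEL_GM)
        n_flip = int(round(params.cortical_thinning * gm_flat.size))
        if n_flip > 0:
            order = np.argsort(-r.ravel()[gm_flat], kind="stable")
            flip = gm_flat[order[:n_flip]]
            labels.ravel()[flip] = LABEL_CSF

    for name, lab in _TISSUE_LABEL.items():
        if not np.any(labels == lab):
            raise ValueError(f"grid {shape} too small: {name} compartment is empty")
    if params.ventricle_scale > 0 and not ventricle.any():
        raise ValueError(f"grid {shape} too small: ventricle compartment is empty")

    rng = np.random.default_rng(params.seed)
    ct = np.zeros(shape, dtype=np.float64)
    for name, lab in _TISSUE_LABEL.items():
        ct[labels == lab] = params.tissue_means[name]
    if params.noise_sd > 0:
        in_brain = labels != LABEL_BACKGROUND
        ct[in_brain] += rng.normal(0.0, params.noise_sd, size=int(in_brain.sum()))

    return PhantomSubject(
        ct=CTVolume(ct, voxel_size_mm=params.voxel_size_mm),
        labels=LabelVolume(labels, voxel_size_mm=params.voxel_size_mm),
        ventricle_mask=ventricle,
        params=params,
    )


def severity_to_score(severity: float, region: str) -> int:
    """Map a severity in [0, 1] onto the region's ordinal scale.

    Equal-width bins: FA/PA use 4 bins on [0, 1] -> scores 0-3; MTA uses
    5 bins -> scores 0-4.  The mapping is monotone and invertible per bin.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    smax = REGION_SCALE_MAX[region]
    return min(smax, int(np.floor(severity * (smax + 1))))


def _draw_severities(spec, rng: np.random.Generator) -> dict[str, float]:
    """One subject's per-region severities.

    ``spec`` may be None (default two-factor model: a cortical factor
    shared by FA/PA and a temporal factor shared by MTAR/MTAL, each
    uniform on [0, 1], plus small independent jitter), a mapping
    region -> ("constant", v) | ("uniform", lo, hi) | ("beta", a, b)
    for independent draws, or a callable rng -> {region: severity}.
    """
    if callable(spec):
        out = dict(spec(rng))
        if set(out) != set(REGIONS):
            raise ValueError(f"severity callable must return all regions {REGIONS}")
        return out
    if spec is None:
        cortical = rng.uniform(0.0, 1.0)
        temporal = rng.uniform(0.0, 1.0)
        jitter = 0.15
        factor = {"FA": cortical, "PA": cortical, "MTAR": temporal, "MTAL": temporal}
        return {
            reg: float(np.clip(factor[reg] + jitter * (rng.uniform() - 0.5), 0.0, 1.0))
            for reg in REGIONS
        }
    out = {}
    for reg in REGIONS:
        kind, *args = spec[reg]
        if kind == "constant":
            out[reg] = float(args[0])
        elif kind == "uniform":
            out[reg] = float(rng.uniform(args[0], args[1]))
        elif kind == "beta":
            out[reg] = float(rng.beta(args[0], args[1]))
        else:
            raise ValueError(f"unknown severity distribution kind {kind!r}")
        if not 0.0 <= out[reg] <= 1.0:
            raise ValueError(f"severity draw for {reg} outside [0, 1]: {out[reg]}")
    return out


def simulate_cohort(
    n: int,
    severity_distribution=None,
    rating_noise: float = 0.05,
    seed: int = 0,
    *,
    base_params: PhantomParams | None = None,
    ventricle_gain: float = 0.8,
    thinning_gain: float = 0.35,
    gm_thickness_range: tuple[float, float] = (0.15, 0.21),
) -> list[PhantomSubject]:
    """Simulate a rated cohort of phantom subjects.

    Geometry coupling (deterministic, monotone in severity):
    ``ventricle_scale = 1 + ventricle_gain * mean(MTAR, MTAL severity)``
    and ``cortical_thinning = thinning_gain * mean(FA, PA severity)``.
    The GM rind thickness is additionally jittered per subject within
    ``gm_thickness_range`` as severity-independent anatomical variation.

    Each VRS score is the equal-width-bin image of the region's severity;
    with probability ``rating_noise`` it is then perturbed by one step
    (direction uniform), clamped to the scale.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= rating_noise <= 0.5:
        raise ValueError(f"rating_noise must be in [0, 0.5], got {rating_noise}")
    base = base_params or PhantomParams()
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=n)

    subjects: list[PhantomSubject] = []
    for i in range(n):
        rng = np.random.default_rng(subject_seeds[i])
        sev = _draw_severities(severity_distribution, rng)
        vscale = 1.0 + ventricle_gain * 0.5 * (sev["MTAR"] + sev["MTAL"])
        thinning = thinning_gain * 0.5 * (sev["FA"] + sev["PA"])
        gm_thick = float(rng.uniform(*gm_thickness_range))
        params = PhantomParams(
            grid_shape=base.grid_shape,
            ventricle_scale=vscale,
            cortical_thinning=thinning,
            noise_sd=base.noise_sd,
            tissue_means=dict(base.tissue_means),
            seed=int(rng.integers(0, 2**31 - 1)),
            gm_thickness=gm_thick,
            voxel_size_mm=base.voxel_size_mm,
        )
        subj = generate_phantom(params)
        subj.subject_id = f"sub-{i:04d}"
        subj.true_severity = sev
        subj.ratings = []
        for reg in REGIONS:
            score = severity_to_score(sev[reg], reg)
            if rating_noise > 0 and rng.uniform() < rating_noise:
                step = 1 if rng.uniform() < 0.5 else -1
                score = int(np.clip(score + step, 0, REGION_SCALE_MAX[reg]))
            subj.ratings.append(
                RatingRecord(
                    subject_id=subj.subject_id,
                    region=reg,
                    vrs_score=score,
                    binary_label=binarize_vrs(score, reg),
                )
            )
        subjects.append(subj)
    return subjects
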