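"""Seeded synthetic LGG cohorts: ADC tumor volumes, masks and VASARI records.

The generator stands in for an (unavailable) patient cohort.  It emulates a
two-class population — IDH1-mutant vs IDH1-wildtype lower-grade glioma — with
planted, independently controllable class signal in four radiomics feature
families plus the class-conditional VASARI trait distributions:

* histogram family: the wildtype per-subject minimum ADC is shifted down by
  ``histogram_min_shift`` and wildtype tumors carry low-ADC necrosis-like
  foci at rate ``necrosis_focus_rate``;
* run/zone texture family: mutant tumors have a longer spatial correlation
  length (``texture_length_delta`` added to the base Gaussian kernel width),
  hence longer runs and larger zones;
* shape family: wildtype tumors are more eccentric (``eccentricity_shift``
  added to the radial anisotropy).

To keep these channels orthogonal, the in-mask intensity field is
rank-gaussianized after smoothing: every subject's marginal intensity
distribution is the same Gaussian quantile grid regardless of the texture
kernel, so texture effects do not leak into first-order histogram features,
and the ellipsoid radii are normalized to constant product so eccentricity
does not leak into volume.  With every effect set to zero the two classes
are drawn from identical distributions.

Randomness is one global stream split hierarchically: subject ``i`` draws
from ``SeedSequence(seed, spawn_key=(1, i))``, so a subject's data do not
depend on the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .types import (
    LABELS,
    MUTANT,
    WILDTYPE,
    ConfigurationError,
    GenerationError,
    MaskedVolume,
)
from .vasari import DEFAULT_LEXICON, VASARILexicon


@dataclass
class ClassEffects:
    """Per-feature-family class effect sizes.

    All effects act on the wildtype class relative to the mutant class
    except ``texture_length_delta``, which lengthens the mutant correlation
    kernel.  Zero everywhere means the two classes are indistinguishable.
    """

    histogram_min_shift: float = -0.05  # 10^-3 mm^2/s, added to wildtype minima
    necrosis_focus_rate: float = 0.8    # expected low-ADC foci per wildtype tumor
    texture_length_delta: float = 0.12  # extra smoothing sigma (voxels) for mutants
    eccentricity_shift: float = 0.30    # extra radial anisotropy for wildtype
    vasari_effect: float = 1.0          # 0 = identical VASARI conditionals
    clinical_age_shift: float = 4.1     # years added to wildtype mean age

    @classmethod
    def zero(cls) -> "ClassEffects":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _default_vasari_conditionals(lexicon: VASARILexicon) -> dict:
    """Class-conditional category probabilities for all 23 traits.

    The five traits the genotype is known to express through imaging carry
    class contrast (wildtype: more enhancement, deep white matter invasion,
    necrosis, infiltrative T1/FLAIR pattern; mutant: frontal predominance);
    the remaining traits share one plausible distribution for both classes.
    """
    cond: dict[str, dict[str, list[float]]] = {}
    for trait in lexicon.trait_names:
        k = len(lexicon.categories(trait))
        if k == 2:
            base = [0.8, 0.2]
        else:
            base = [2.0] + [1.0] * (k - 1)
            base = [b / sum(base) for b in base]
        cond[trait] = {MUTANT: list(base), WILDTYPE: list(base)}
    cond["enhancement quality"] = {
        MUTANT: [0.7, 0.2, 0.1],
        WILDTYPE: [0.1, 0.2, 0.7],
    }
    cond["deep white matter invasion"] = {
        MUTANT: [0.85, 0.15],
        WILDTYPE: [0.45, 0.55],
    }
    cond["tumor location"] = {
        MUTANT: [0.55, 0.14, 0.08, 0.03, 0.06, 0.02, 0.02, 0.10],
        WILDTYPE: [0.20, 0.25, 0.12, 0.08, 0.12, 0.08, 0.05, 0.10],
    }
    cond["proportion of necrosis"] = {
        MUTANT: [0.70, 0.15, 0.10, 0.03, 0.01, 0.01],
        WILDTYPE: [0.30, 0.25, 0.25, 0.12, 0.05, 0.03],
    }
    cond["T1/FLAIR ratio"] = {
        MUTANT: [0.60, 0.30, 0.10],
        WILDTYPE: [0.15, 0.45, 0.40],
    }
    return cond


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic cohort draw."""

    n_subjects: int = 102
    mutant_fraction: float = 50 / 102
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range: tuple[float, float] = (6.0, 12.0)  # mm
    adc_background_mean: float = 1.2   # 10^-3 mm^2/s, plausible LGG range
    adc_background_sd: float = 0.15
    necrosis_mean: float = 0.6
    necrosis_sd: float = 0.1
    texture_base_sigma: float = 1.0    # smoothing kernel sd (voxels), wildtype
    intensity_jitter: float = 0.05     # sd of per-subject background-mean offset
    scale_jitter: float = 0.10         # sd of per-subject log background-sd offset
    shape_jitter: float = 2.0          # sd of per-subject skew-normal shape alpha
    base_anisotropy: float = 0.15      # log-uniform radial anisotropy, both classes
    mean_age: float = 43.2             # mutant mean age (years)
    age_sd: float = 16.3
    male_fraction: float = 60 / 102
    class_effects: ClassEffects = field(default_factory=ClassEffects)
    vasari_conditionals: dict | None = None
    lexicon: VASARILexicon = field(default_factory=lambda: DEFAULT_LEXICON)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vasari_conditionals is None:
            self.vasari_conditionals = _default_vasari_conditionals(self.lexicon)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ConfigurationError("n_subjects must be >= 4")
        if not 0.0 < self.mutant_fraction < 1.0:
            raise ConfigurationError("mutant_fraction must be in (0, 1)")
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise ConfigurationError("volume_shape must be three dims >= 8")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("voxel_spacing must be positive")
        lo, hi = self.tumor_radius_range
        if not 0 < lo <= hi:
            raise ConfigurationError("tumor_radius_range must satisfy 0 < lo <= hi")
        for name in ("adc_background_sd", "necrosis_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.class_effects.necrosis_focus_rate < 0:
            raise ConfigurationError("necrosis_focus_rate must be >= 0")
        for trait in self.lexicon.trait_names:
            if trait not in self.vasari_conditionals:
                raise ConfigurationError(f"vasari_conditionals missing trait {trait!r}")
            row = self.vasari_conditionals[trait]
            k = len(self.lexicon.categories(trait))
            for cls in LABELS:
                probs = row[cls]
                if len(probs) != k:
                    raise ConfigurationError(
                        f"vasari_conditionals[{trait!r}][{cls!r}] must have {k} entries"
                    )
                if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                    raise ConfigurationError(
                        f"vasari_conditionals[{trait!r}][{cls!r}] must sum to 1"
                    )


@dataclass
class SyntheticSubject:
    id: str
    volume: MaskedVolume
    vasari: dict
    label: str
    age: float
    gender: str  # "male" / "female"


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    config: SyntheticConfig

    def labels(self) -> dict[str, str]:
        return {s.id: s.label for s in self.subjects}

    def radiomics_subjects(self) -> list[tuple[str, MaskedVolume, str]]:
        return [(s.id, s.volume, s.label) for s in self.subjects]

    def vasari_records(self) -> dict[str, dict]:
        return {s.id: s.vasari for s in self.subjects}


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, index)))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _rank_remap(values: np.ndarray, alpha: float) -> np.ndarray:
    """Map values onto a zero-mean unit-sd skew-normal quantile grid.

    Preserving ranks decouples the marginal intensity distribution from the
    spatial correlation structure, so texture effects cannot leak into
    first-order histogram features; the per-subject shape parameter ``alpha``
    gives histograms the natural between-subject variation in skewness and
    kurtosis that real ADC distributions show.
    """
    order = np.argsort(values, kind="stable")
    grid = stats.skewnorm.ppf(
        (np.arange(values.size) + 0.5) / values.size, a=alpha
    )
    grid = (grid - grid.mean()) / grid.std()
    out = np.empty_like(values)
    out[order] = grid
    return out


def generate_tumor_volume(
    label: str, config: SyntheticConfig, rng: np.random.Generator
) -> MaskedVolume:
    """One rotated-ellipsoid tumor with class-dependent intensity structure."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    eff = config.class_effects
    shape = tuple(config.volume_shape)
    spacing = np.asarray(config.voxel_spacing, dtype=float)

    r = rng.uniform(*config.tumor_radius_range)
    aniso = config.base_anisotropy + (eff.eccentricity_shift if label == WILDTYPE else 0.0)
    g = np.exp(rng.uniform(-aniso, aniso, size=3))
    g /= np.prod(g) ** (1 / 3)  # constant product: eccentricity leaves volume alone
    radii = r * g
    extent = np.asarray(shape) * spacing
    if np.any(2 * radii.max() >= extent.min()):
        raise GenerationError(
            f"tumor radii {radii} do not fit into the volume extent {extent}"
        )
    rot = _random_rotation(rng)
    center = (np.asarray(shape) - 1) / 2.0 * spacing
    coords = (
        np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
        * spacing
        - center
    )
    local = coords @ rot.T / radii
    mask = (local**2).sum(axis=-1) <= 1.0
    if not mask.any():
        raise GenerationError("generated mask is empty; enlarge tumor_radius_range")

    sigma = config.texture_base_sigma + (
        eff.texture_length_delta if label == MUTANT else 0.0
    )
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma)
    intensities = rng.normal(0.8, 0.1, size=shape)  # background brain-like values
    # class-independent per-subject variation of the marginal ADC distribution
    alpha = rng.normal(0.0, config.shape_jitter)
    subj_mean = config.adc_background_mean + rng.normal(0.0, config.intensity_jitter)
    subj_sd = config.adc_background_sd * np.exp(rng.normal(0.0, config.scale_jitter))
    z = _rank_remap(noise[mask], alpha)
    intensities[mask] = subj_mean + subj_sd * z

    if label == WILDTYPE and eff.necrosis_focus_rate > 0:
        n_foci = rng.poisson(eff.necrosis_focus_rate)
        in_mask = np.argwhere(mask)
        for _ in range(n_foci):
            c = in_mask[rng.integers(len(in_mask))] * spacing
            fr = rng.uniform(1.5, 3.5)
            focus = mask & (((coords + center - c) ** 2).sum(axis=-1) <= fr**2)
            intensities[focus] = rng.normal(
                config.necrosis_mean, config.necrosis_sd, size=int(focus.sum())
            )

    if label == WILDTYPE and eff.histogram_min_shift != 0.0:
        # deepen the darkest end of the wildtype distribution by a per-subject
        # random amount averaging histogram_min_shift; the dip is a smooth
        # blend so it is not a deterministic zone signature
        cur_min = intensities[mask].min()
        shift = rng.normal(eff.histogram_min_shift, 0.4 * abs(eff.histogram_min_shift))
        shift = -abs(shift)
        in_mask = np.argwhere(mask)
        c = in_mask[rng.integers(len(in_mask))] * spacing
        dip_r = rng.uniform(1.5, 3.0)
        d2 = ((coords + center - c) ** 2).sum(axis=-1)
        blend = np.clip(1.0 - np.sqrt(d2) / dip_r, 0.0, 1.0) * mask
        target = cur_min + shift
        intensities = np.minimum(
            intensities, intensities * (1 - blend) + target * blend
        )

    np.maximum(intensities, 0.0, out=intensities)
    return MaskedVolume(intensities, mask, tuple(spacing))


def generate_vasari_record(
    label: str, config: SyntheticConfig, rng: np.random.Generator
) -> dict:
    """Sample all 23 traits from their class-conditional multinomials.

    ``vasari_effect`` interpolates each class row toward the two-class
    mixture, so 0 yields identical conditionals for both classes.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    e = config.class_effects.vasari_effect
    record = {}
    for trait in config.lexicon.trait_names:
        row = config.vasari_conditionals[trait]
        p_cls = np.asarray(row[label], dtype=float)
        p_mix = (np.asarray(row[MUTANT], dtype=float) + np.asarray(row[WILDTYPE])) / 2
        p = (1 - e) * p_mix + e * p_cls
        p /= p.sum()
        cats = config.lexicon.categories(trait)
        record[trait] = cats[rng.choice(len(cats), p=p)]
    return record


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a full cohort: labels, tumor volumes, VASARI records, clinicals."""
    config.validate()
    cohort_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
    )
    n = config.n_subjects
    n_mut = int(round(n * config.mutant_fraction))
    n_mut = min(max(n_mut, 1), n - 1)  # both classes always present
    labels = np.array([MUTANT] * n_mut + [WILDTYPE] * (n - n_mut))
    cohort_rng.shuffle(labels)

    subjects = []
    for i, label in enumerate(labels):
        rng = _subject_rng(config.seed, i)
        volume = generate_tumor_volume(label, config, rng)
        vasari = generate_vasari_record(label, config, rng)
        age_mean = config.mean_age + (
            config.class_effects.clinical_age_shift if label == WILDTYPE else 0.0
        )
        age = float(np.clip(rng.normal(age_mean, config.age_sd), 18.0, 77.0))
        gender = "male" if rng.random() < config.male_fraction else "female"
        subjects.append(
            SyntheticSubject(f"subj{i:03d}", volume, vasari, str(label), age, gender)
        )
    return SyntheticCohort(subjects, config)


def perturb_mask(
    mask: np.ndarray, severity: float, rng: np.random.Generator
) -> np.ndarray:
    """Simulate a second rater's contour of the same tumor.

    Voxels are flipped with probability ``min(1, severity / (1 + d^2))``
    where ``d`` is the voxel's distance to the mask boundary, modulated by a
    smooth spatial noise field so flips form contiguous contour deviations
    rather than speckle.  Severity 0 returns the mask unchanged; the flip
    probability decays quadratically with boundary distance, so the deep
    interior (and far exterior) is untouched at moderate severity; as
    severity grows every voxel flips and the overlap vanishes.
    """
    mask = np.asarray(mask, dtype=bool)
    if severity < 0:
        raise ValueError("severity must be >= 0")
    if not mask.any():
        raise ValueError("mask is empty")
    if severity == 0:
        return mask.copy()
    dist = np.where(
        mask, ndimage.distance_transform_edt(mask), ndimage.distance_transform_edt(~mask)
    )
    p_flip = np.minimum(1.0, severity / (1.0 + dist**2))
    # finite reach: voxels beyond it never flip, growing with severity so the
    # far interior/exterior is exactly preserved at moderate severity while
    # arbitrarily large severity still flips everything
    p_flip[dist > 2.0 + 3.0 * np.sqrt(severity)] = 0.0
    eta = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=1.5)
    eta /= eta.std()
    u = stats.norm.cdf(eta)
    return mask ^ (u < p_flip)


def calibrate_severity(
    masks: list[np.ndarray],
    target_dsc: float,
    seed: int = 0,
    lo: float = 1e-3,
    hi: float = 50.0,
    iterations: int = 20,
) -> float:
    """Bisection search for the severity whose mean DSC matches ``target_dsc``.

    Mean DSC against the original masks decreases monotonically in severity
    (in expectation), so a bisection on the mean over the given masks
    converges to the severity reproducing a desired interobserver regime.
    """
    from .agreement import dice

    def mean_dsc(s: float) -> float:
        rng = np.random.default_rng(seed)
        return float(
            np.mean([dice(m, perturb_mask(m, s, rng)).dsc for m in masks])
        )

    for _ in range(iterations):
        mid = np.sqrt(lo * hi)
        if mean_dsc(mid) > target_dsc:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
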