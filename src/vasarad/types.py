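"""Core containers shared across the package.

A :class:`MaskedVolume` couples a 3-D apparent-diffusion-coefficient (ADC)
map (units 10^-3 mm^2/s) with a co-registered binary tumor mask and the voxel
spacing in mm.  A :class:`FeatureTable` holds per-subject feature values
(radiomics or encoded VASARI scores) together with the binary IDH1 genotype
label and, once fitted, the min/max normalization bounds of each column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MUTANT = "mutant"
WILDTYPE = "wildtype"
LABELS = (MUTANT, WILDTYPE)


class ConfigurationError(ValueError):
    """Raised when a configuration field violates its contract."""


class GenerationError(RuntimeError):
    """Raised when a synthetic object cannot be generated as requested."""


@dataclass
class MaskedVolume:
    """A 3-D intensity volume restricted to a tumor volume of interest."""

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if self.intensities.shape != self.mask.shape:
            raise ValueError("mask shape must match intensity shape")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive mm values")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground voxel")
        if not np.all(np.isfinite(self.intensities[self.mask])):
            raise ValueError("in-mask intensities must be finite")

    @property
    def values(self) -> np.ndarray:
        """In-mask voxel intensities as a flat array."""
        return self.intensities[self.mask]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class FeatureTable:
    """Subjects x features matrix plus labels and normalization bounds.

    ``bounds`` maps a feature name to the (min, max) used in the [0, 1]
    rescaling; it is fitted on the training cohort and reused verbatim on
    validation data.  ``degenerate`` records constant columns, which are
    mapped to zero rather than dividing by a zero range.
    """

    data: pd.DataFrame
    labels: pd.Series
    bounds: dict[str, tuple[float, float]] | None = None
    degenerate: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("labels index must match data index")
        if self.data.isna().any().any():
            raise ValueError("feature table must not contain missing cells")
        bad = set(self.labels.unique()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    def subset(self, ids) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(
            self.data.loc[ids].copy(),
            self.labels.loc[ids].copy(),
            bounds=self.bounds,
            degenerate=self.degenerate,
        )

    def select_features(self, names) -> "FeatureTable":
        names = list(names)
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        bounds = None
        if self.bounds is not None:
            bounds = {n: self.bounds[n] for n in names if n in self.bounds}
        return FeatureTable(
            self.data[names].copy(), self.labels.copy(), bounds=bounds,
            degenerate=frozenset(n for n in self.degenerate if n in names),
        )

    def label_array(self) -> np.ndarray:
        """Labels as 0/1 with wildtype as the positive class."""
        return (self.labels.to_numpy() == WILDTYPE).astype(int)
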