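"""Extraction configuration, feature keys, and the feature-count bookkeeping.

The pinned default configuration yields exactly 1409 features per masked
image: 93 intensity features (18 first-order + 24 GLCM + 16 GLRLM +
16 GLSZM + 14 GLDM + 5 NGTDM) computed on the original image and on each of
14 derived image types (8 wavelet sub-bands, square, squareroot, logarithm,
exponential, gradient, LBP-2D), plus 14 shape descriptors on the original
image only: 1409 = 15 × 93 + 14.

``log_of_gaussian`` and ``lbp3d`` sit in the default filter list but
contribute no derived images until smoothing scales / the 3-D LBP flag are
supplied explicitly (doing so changes the per-image count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from ..errors import ConfigurationError

ALL_FILTERS = (
    "original",
    "wavelet",
    "log_of_gaussian",
    "square",
    "squareroot",
    "logarithm",
    "exponential",
    "gradient",
    "lbp2d",
    "lbp3d",
)

ALL_CLASSES = ("firstorder", "shape", "glcm", "glrlm", "ngtdm", "gldm", "glszm")

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

# per-class feature counts for the pinned feature sets
CLASS_SIZES = {
    "firstorder": 18,
    "shape": 14,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}


class FeatureKey(NamedTuple):
    """Full provenance of one feature value within a cohort table.

    ``reader`` is carried at the table level during cohort extraction (the
    two per-reader tables share identical column keys) and re-attached on
    CSV export.
    """

    phase: str
    compartment: str
    resolution_mm: float
    filter: str
    feature_class: str
    feature_name: str


KEY_FIELDS = ("phase", "compartment", "resolution_mm", "filter", "feature_class", "feature_name")


@dataclass(frozen=True)
class ExtractionConfig:
    filters: tuple[str, ...] = ALL_FILTERS
    feature_classes: tuple[str, ...] = ALL_CLASSES
    bin_width: float = 25.0
    resolutions_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    shape_on_original_only: bool = True
    log_sigmas_mm: tuple[float, ...] = ()
    enable_lbp3d: bool = False

    def validate(self) -> None:
        for f in self.filters:
            if f not in ALL_FILTERS:
                raise ConfigurationError(f"unknown filter {f!r}; valid: {ALL_FILTERS}")
        for c in self.feature_classes:
            if c not in ALL_CLASSES:
                raise ConfigurationError(f"unknown feature class {c!r}; valid: {ALL_CLASSES}")
        if len(set(self.filters)) != len(self.filters):
            raise ConfigurationError("duplicate entries in filters")
        if len(set(self.feature_classes)) != len(self.feature_classes):
            raise ConfigurationError("duplicate entries in feature_classes")
        if self.bin_width <= 0:
            raise ConfigurationError(f"bin_width must be > 0, got {self.bin_width}")
        if not self.resolutions_mm or any(r <= 0 for r in self.resolutions_mm):
            raise ConfigurationError(f"resolutions_mm must be positive, got {self.resolutions_mm}")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ConfigurationError(f"log_sigmas_mm must be positive, got {self.log_sigmas_mm}")


def image_types(config: ExtractionConfig) -> list[str]:
    """Ordered derived-image names produced by the configured filters."""
    config.validate()
    out: list[str] = []
    for f in config.filters:
        if f == "original":
            out.append("original")
        elif f == "wavelet":
            out.extend(f"wavelet-{sb}" for sb in WAVELET_SUBBANDS)
        elif f == "log_of_gaussian":
            out.extend(f"log-sigma-{s:g}mm" for s in config.log_sigmas_mm)
        elif f == "lbp3d":
            if config.enable_lbp3d:
                out.append("lbp-3D")
        elif f == "lbp2d":
            out.append("lbp-2D")
        else:
            out.append(f)
    return out


def n_features_per_image(config: ExtractionConfig) -> int:
    """Feature count for one masked image under ``config``."""
    intensity = sum(CLASS_SIZES[c] for c in config.feature_classes if c != "shape")
    types = image_types(config)
    total = intensity * len(types)
    if "shape" in config.feature_classes:
        if config.shape_on_original_only:
            total += CLASS_SIZES["shape"] * ("original" in types)
        else:
            total += CLASS_SIZES["shape"] * len(types)
    return total
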