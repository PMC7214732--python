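"""Rule-based classification of image objects into vein and background.

The knowledge base is a three-stage cascade of inclusive threshold rules,
applied in a fixed order; each stage refines the previous one:

1. **Brightness** — objects whose brightness lies in
   ``[brightness_min, brightness_max]`` (default 230..280) become vein
   candidates, everything else background.
2. **Spectral** — candidates whose red-band mean falls below ``red_min``
   (default 180; an upper bound is optional and disabled by default) are
   demoted to background.
3. **Geometric** — surviving candidates are merged into 4-connected
   components; components whose density feature is at most ``density_max``
   (default 2) are veins, the rest background.

The default thresholds are the recommended universal values for cleared,
stained leaf micrographs across species; note the brightness range assumes
intensities on the stretched scale and the upper brightness bound is not
binding for 8-bit data.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import yaml

from . import features
from .segmentation import SegmentationLevel, merge_objects

VEIN = "vein"
VEIN_CANDIDATE = "vein_candidate"
BACKGROUND = "background"


@dataclasses.dataclass(frozen=True)
class RuleSet:
    """Thresholds of the three-stage cascade.  All bounds inclusive."""

    brightness_min: float = 230.0
    brightness_max: float = 280.0
    red_min: float = 180.0
    red_max: float | None = None
    density_max: float = 2.0

    def __post_init__(self) -> None:
        if self.brightness_min > self.brightness_max:
            raise ValueError("brightness_min must not exceed brightness_max")
        if self.red_max is not None and self.red_min > self.red_max:
            raise ValueError("red_min must not exceed red_max")
        if self.density_max <= 0:
            raise ValueError("density_max must be positive")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RuleSet":
        return cls(**{k: d[k] for k in d})

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclasses.dataclass
class ClassMap:
    """Per-object labels plus the rule that assigned each of them."""

    labels: np.ndarray       # array of str, indexed by object id
    provenance: np.ndarray   # array of str, rule names

    def ids_with(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    @property
    def vein_ids(self) -> np.ndarray:
        return self.ids_with(VEIN)

    def pixel_mask(self, level: SegmentationLevel, label: str) -> np.ndarray:
        """Binary raster of the pixels of all objects carrying ``label``."""
        return np.isin(level.labels, self.ids_with(label))


def classify_brightness(level: SegmentationLevel, rules: RuleSet) -> ClassMap:
    """Stage 1: brightness window selects vein candidates."""
    ft = features.feature_table(level)
    ok = (ft["brightness"] >= rules.brightness_min) & (
        ft["brightness"] <= rules.brightness_max
    )
    labels = np.where(ok, VEIN_CANDIDATE, BACKGROUND).astype(object)
    prov = np.where(ok, "brightness:in-range", "brightness:out-of-range").astype(object)
    return ClassMap(labels, prov)


def refine_spectral(
    level: SegmentationLevel, cm: ClassMap, rules: RuleSet
) -> ClassMap:
    """Stage 2: red-band window demotes off-spectrum candidates."""
    ft = features.feature_table(level)
    labels = cm.labels.copy()
    prov = cm.provenance.copy()
    cand = labels == VEIN_CANDIDATE
    bad = cand & (ft["mean_red"].to_numpy() < rules.red_min)
    if rules.red_max is not None:
        bad |= cand & (ft["mean_red"].to_numpy() > rules.red_max)
    labels[bad] = BACKGROUND
    prov[bad] = "spectral:red-out-of-range"
    return ClassMap(labels, prov)


def refine_geometric(
    level: SegmentationLevel, cm: ClassMap, rules: RuleSet
) -> tuple[SegmentationLevel, ClassMap]:
    """Stage 3: merge candidates into components; keep the elongated ones.

    Candidates are fused into 4-connected components (as in
    :func:`veinseg.segmentation.merge_objects`), and each component with
    density at most ``rules.density_max`` is labelled vein.  Because merging
    renumbers objects, a new level is returned together with the class map
    for it.
    """
    cand_ids = cm.ids_with(VEIN_CANDIDATE)
    if cand_ids.size == 0:
        labels = np.full(level.n_objects, BACKGROUND, dtype=object)
        prov = cm.provenance.copy()
        return level, ClassMap(labels, prov)

    cand_mask = np.isin(level.labels, cand_ids)
    merged = merge_objects(level, cand_ids)
    comp_ids = np.unique(merged.labels[cand_mask])

    ft = features.feature_table(merged)
    dens = ft["density"].to_numpy()
    labels = np.full(merged.n_objects, BACKGROUND, dtype=object)
    prov = np.full(merged.n_objects, "carried:background", dtype=object)
    is_vein = dens[comp_ids] <= rules.density_max
    labels[comp_ids[is_vein]] = VEIN
    prov[comp_ids[is_vein]] = "geometric:density-in-range"
    prov[comp_ids[~is_vein]] = "geometric:density-too-high"
    return merged, ClassMap(labels, prov)


def classify(
    level: SegmentationLevel, rules: RuleSet | None = None
) -> tuple[SegmentationLevel, ClassMap]:
    """Run the full brightness -> spectral -> geometric cascade."""
    rules = rules or RuleSet()
    cm = classify_brightness(level, rules)
    cm = refine_spectral(level, cm, rules)
    return refine_geometric(level, cm, rules)
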