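"""Seeded synthetic cohorts for the weakly-supervised MIL pipeline.

Each synthetic patient carries a 3D volume (a bag of axial slices), a
clinical/dosimetric row, a high-dimensional engineered-feature row, and a
binary bag label.  The bag label obeys the standard MIL constraint: it is 1
iff at least one slice carries a planted lesion.  Lesions are bright
ellipsoidal patches confined to single slices so the signal is
slice-attributable, matching the slice-as-instance premise.

The clinical table mimics a thoracic-radiotherapy cohort: six categorical
null features (age group, smoking, chemotherapy, histology, T/N stage) that
carry no class signal, and five continuous dose-volume metrics (V5-V30 and
mean lung dose) whose positive-class mean shifts default to the modest
differences typical of such cohorts.  The engineered-feature table is
Gaussian noise with additive class shifts in a small set of informative
columns, which makes sparse-recovery behaviour of the lasso directly
testable.

One integer seed drives everything through named sub-streams, so a config
reproduces its cohort bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .tabular import CATEGORICAL, CONTINUOUS, FeatureTable

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort",
           "bag_label_from_instances", "plant_key_slices"]

# dose-volume metric templates: (name, control mean, SD)
_DOSIMETRIC = [
    ("lung_v5", 43.75, 13.65),
    ("lung_v10", 31.15, 10.25),
    ("lung_v20", 20.09, 7.38),
    ("lung_v30", 13.17, 5.22),
    ("lung_dmean", 10.82, 3.40),
]
# categorical null features: (name, Bernoulli probability of level 1)
_CATEGORICAL = [
    ("age_ge_65", 0.45),
    ("smoking", 0.42),
    ("chemotherapy", 0.67),
    ("histology_scc", 0.39),
    ("t_stage_34", 0.35),
    ("n_stage_23", 0.69),
]


@dataclass
class CohortConfig:
    n_patients: int = 670
    prevalence: float = 270 / 670
    volume_shape: tuple = (32, 32, 16)
    key_slice_range: tuple = (1, 2)
    lesion_effect: float = 3.0
    clinical_effect_sizes: tuple = (2.68, 2.19, 1.77, 1.34, 0.81)
    n_radiomics: int = 758
    n_radiomics_informative: int = 15
    radiomics_effect: float = 0.8
    noise_sd: float = 1.0
    # fixed bright in-slice frame (body/bone analog) anchoring the intensity
    # range so per-volume min-max rescaling carries no bag-level cue
    anchor_intensity: float = 8.0
    seed: int = 0

    def validate(self):
        if not 0 < self.prevalence < 1:
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 1:
            raise ConfigurationError("volume_shape must be three positive counts")
        lo, hi = self.key_slice_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("key_slice_range must satisfy 1 <= min <= max")
        if hi > self.volume_shape[2]:
            raise ConfigurationError("more key slices than volume depth")
        if self.n_radiomics_informative > self.n_radiomics:
            raise ConfigurationError("informative columns exceed table width")
        if self.n_patients < 1 or self.n_radiomics < 1:
            raise ConfigurationError("counts must be positive")
        if len(self.clinical_effect_sizes) != len(_DOSIMETRIC):
            raise ConfigurationError(
                f"expected {len(_DOSIMETRIC)} dosimetric effect sizes")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


@dataclass
class GroundTruth:
    instance_labels: list            # per patient: length-depth {0,1} vector
    bag_labels: np.ndarray           # per patient binary label
    key_slice_indices: list = field(default_factory=list)

    def to_json(self, path):
        payload = {
            "bag_labels": [int(v) for v in self.bag_labels],
            "instance_labels": [[int(v) for v in row] for row in self.instance_labels],
            "key_slice_indices": [[int(v) for v in row] for row in self.key_slice_indices],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls([np.array(r, dtype=int) for r in payload["instance_labels"]],
                   np.array(payload["bag_labels"], dtype=int),
                   [list(r) for r in payload["key_slice_indices"]])


def bag_label_from_instances(instance_labels) -> int:
    """MIL constraint: a bag is negative iff every instance is negative."""
    labels = np.asarray(instance_labels)
    if labels.size == 0:
        raise DomainError("empty bag has no defined label")
    if not np.isin(labels, (0, 1)).all():
        raise DomainError("instance labels must be binary")
    return int(labels.any())


def plant_key_slices(volume, indices, effect, centers=None, axes=None):
    """Return a copy of ``volume`` with an additive ellipse on listed slices.

    Only the listed depth slices are modified; the change is +``effect``
    inside a compact elliptical region of each slice.  Geometry defaults to
    a centered ellipse with semi-axes of a quarter of the slice extent.
    """
    volume = np.asarray(volume, dtype=float)
    h, w, depth = volume.shape
    out = volume.copy()
    indices = list(indices)
    for pos, idx in enumerate(indices):
        if not 0 <= idx < depth:
            raise DomainError(f"slice index {idx} outside depth {depth}")
        cy, cx = (centers[pos] if centers is not None else (h / 2.0, w / 2.0))
        ay, ax = (axes[pos] if axes is not None else (h / 4.0, w / 4.0))
        yy, xx = np.ogrid[:h, :w]
        mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        out[:, :, idx][mask] += effect
    return out


def _streams(seed: int, names):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _clinical_table(rng, ids, bag_labels, effects) -> FeatureTable:
    n = len(ids)
    pos = bag_labels == 1
    cols, kinds = {}, {}
    for name, p1 in _CATEGORICAL:
        cols[name] = (rng.random(n) < p1).astype(int)
        kinds[name] = CATEGORICAL
    for (name, mu, sd), shift in zip(_DOSIMETRIC, effects):
        x = rng.normal(mu, sd, size=n)
        x[pos] += shift
        cols[name] = x
        kinds[name] = CONTINUOUS
    return FeatureTable(ids, pd.DataFrame(cols), kinds)


def _radiomics_table(rng, ids, bag_labels, config) -> FeatureTable:
    n = len(ids)
    X = rng.normal(0.0, config.noise_sd, size=(n, config.n_radiomics))
    X[bag_labels == 1, :config.n_radiomics_informative] += config.radiomics_effect
    names = [f"rf_{j:04d}" for j in range(config.n_radiomics)]
    return FeatureTable(ids, pd.DataFrame(X, columns=names),
                        {c: CONTINUOUS for c in names})


def generate_cohort(config: CohortConfig, include_volumes: bool = True):
    """Generate (volumes, clinical_table, radiomics_table, ground_truth).

    ``include_volumes=False`` skips volume synthesis (tables and labels
    only), which keeps large-n tabular experiments cheap.
    """
    config.validate()
    n = config.n_patients
    h, w, depth = config.volume_shape
    rngs = _streams(config.seed,
                    ["labels", "volumes", "lesions", "clinical", "radiomics"])

    bag_labels = (rngs["labels"].random(n) < config.prevalence).astype(int)
    lo, hi = config.key_slice_range
    rng_l = rngs["lesions"]
    instance_labels, key_indices = [], []
    lesion_geom = []
    for label in bag_labels:
        inst = np.zeros(depth, dtype=int)
        if label == 1:
            n_key = int(rng_l.integers(lo, hi + 1))
            idx = sorted(int(v) for v in
                         rng_l.choice(depth, size=n_key, replace=False))
            inst[idx] = 1
            centers = [(rng_l.uniform(0.3 * h, 0.7 * h),
                        rng_l.uniform(0.3 * w, 0.7 * w)) for _ in idx]
            axes = [(rng_l.uniform(h / 8, h / 4), rng_l.uniform(w / 8, w / 4))
                    for _ in idx]
            key_indices.append(idx)
            lesion_geom.append((idx, centers, axes))
        else:
            key_indices.append([])
            lesion_geom.append(([], [], []))
        instance_labels.append(inst)

    truth = GroundTruth(instance_labels, bag_labels, key_indices)
    ids = np.array([f"P{i:04d}" for i in range(n)])
    clinical = _clinical_table(rngs["clinical"], ids, bag_labels,
                               config.clinical_effect_sizes)
    radiomics = _radiomics_table(rngs["radiomics"], ids, bag_labels, config)

    volumes = None
    if include_volumes:
        volumes = rngs["volumes"].normal(0.0, config.noise_sd, size=(n, h, w, depth))
        volumes[:, 0, :, :] = config.anchor_intensity
        volumes[:, -1, :, :] = config.anchor_intensity
        volumes[:, :, 0, :] = config.anchor_intensity
        volumes[:, :, -1, :] = config.anchor_intensity
        for i, (idx, centers, axes) in enumerate(lesion_geom):
            if idx:
                volumes[i] = plant_key_slices(volumes[i], idx,
                                              config.lesion_effect,
                                              centers=centers, axes=axes)
    return volumes, clinical, radiomics, truth
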