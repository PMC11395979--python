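"""Configuration objects for cohort simulation and pipeline runs.

Units are fixed throughout the package: diameters in mm, velocities in m/s,
pressures in kPa.  Nothing converts implicitly; the mmHg helpers in
:mod:`aortameta.hemo` are the only unit conversions.

The default class-conditional diameter parameters below are SYNTHETIC: they
are not patient-derived.  They encode the qualitative separations reported
for infant thoracic aortas — in coarctation (CoA) the minimal descending
diameter D0 is markedly smaller (and less spread), the distal-arch D3 and
ascending D1 are somewhat smaller, while the brachiocephalic origin DBCA
(more spread) and the hiatus-level D5 are larger.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

#: The nine landmark diameters, in canonical CSV column order.
DIAMETER_NAMES: tuple[str, ...] = (
    "D1", "D2", "D3", "D0", "D4", "D5", "DBCA", "DLCCA", "DLSCA",
)

#: The nine sampling domains where velocity and pressure are averaged.
DOMAIN_NAMES: tuple[str, ...] = (
    "P1", "OBCA", "OLCCA", "OLSCA", "M1", "M2", "M3", "M4", "O5",
)

VELOCITY_COLUMNS: tuple[str, ...] = tuple(f"v_{d}" for d in DOMAIN_NAMES)
PRESSURE_COLUMNS: tuple[str, ...] = tuple(f"p_{d}" for d in DOMAIN_NAMES)

LABELS: tuple[str, str] = ("normal", "coa")

#: Canonical cohort CSV column order: identifiers, diameters (mm),
#: velocities (m/s), pressures (kPa).
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id", "label", *DIAMETER_NAMES, *VELOCITY_COLUMNS,
    *PRESSURE_COLUMNS,
)

# (mean mm, sd mm) per diameter and class.  Synthetic, infant-scale.
DEFAULT_DIAMETERS: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        "D1": (12.0, 1.5), "D2": (11.0, 1.3), "D3": (9.5, 1.2),
        "D0": (8.5, 1.0), "D4": (10.0, 1.2), "D5": (8.0, 1.0),
        "DBCA": (5.0, 0.8), "DLCCA": (3.5, 0.6), "DLSCA": (4.0, 0.6),
    },
    "coa": {
        "D1": (10.5, 1.5), "D2": (10.5, 1.3), "D3": (8.0, 1.2),
        "D0": (2.5, 0.5), "D4": (10.0, 1.2), "D5": (9.0, 1.0),
        "DBCA": (6.0, 1.2), "DLCCA": (3.6, 0.6), "DLSCA": (4.1, 0.6),
    },
}

# Additive Gaussian noise (generator units) per hemodynamic response.
# Calibrated once so that ratio-feature regressions fitted on default
# 60-record cohorts reach determination coefficients comparable to those of
# CFD-derived data: the branch velocity is the noisiest (it carries rare
# variations no diameter regression captures), the hiatus-level velocity
# the best-predicted (see docs/methods.md).
DEFAULT_NOISE_SD: dict[str, float] = {
    **{c: 0.5 for c in VELOCITY_COLUMNS},
    "v_OBCA": 0.8,
    "v_M4": 0.38,
    **{c: 0.35 for c in PRESSURE_COLUMNS},
}

DEFAULT_FLOW_SPLIT: dict[str, float] = {
    "OBCA": 0.15, "OLCCA": 0.07, "OLSCA": 0.08, "O5": 0.70,
}


def _stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage substream seed from one global seed.

    Uses a CRC of the stage label so that adding or reordering stages never
    shifts the stream another stage consumes.
    """
    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class CohortConfig:
    """Parameters of the synthetic two-class cohort generator.

    Attributes
    ----------
    n_per_class : records per class (study scale: 30 + 30).
    diameters : per-class ``{name: (mean, sd)}`` in mm.
    v_inlet_mean, v_inlet_sd : inlet velocity draw (m/s).
    flow_split : fraction of inlet volume flow leaving through each outlet;
        must sum to 1.
    p_distal_kpa : pressure at the hiatus-level domain before noise.
    friction_kpa : per-station viscous pressure drop.
    stenosis_loss_kpa : scale of the narrowing loss, which grows as
        ``(D3/D0)^4 - 1`` and is placed between the two post-arch stations.
    noise_sd : additive Gaussian noise sd per hemodynamic column.
    hemodynamics_model : ``"balance"`` (mass-balance forward model, default)
        or ``"equation"`` (responses generated from the published regression
        forms; used for identifiability and coverage studies).
    seed : global RNG seed; identical seed and config give identical cohorts.
    """

    n_per_class: int = 30
    diameters: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DIAMETERS.items()})
    v_inlet_mean: float = 0.9
    v_inlet_sd: float = 0.10
    flow_split: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLOW_SPLIT))
    p_distal_kpa: float = 10.5
    friction_kpa: float = 0.10
    stenosis_loss_kpa: float = 0.03
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD))
    hemodynamics_model: str = "balance"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.hemodynamics_model not in ("balance", "equation"):
            raise ValueError(
                f"unknown hemodynamics_model {self.hemodynamics_model!r}")
        if set(self.flow_split) != {"OBCA", "OLCCA", "OLSCA", "O5"}:
            raise ValueError("flow_split must name the four outlets")
        total = sum(self.flow_split.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"flow_split sums to {total}, expected 1")
        for label, params in self.diameters.items():
            if label not in LABELS:
                raise ValueError(f"unknown class label {label!r}")
            for name, (mean, sd) in params.items():
                if name not in DIAMETER_NAMES:
                    raise ValueError(f"unknown diameter {name!r}")
                if mean <= 0:
                    raise ValueError(f"mean of {name} ({label}) must be > 0")
                if sd < 0:
                    raise ValueError(f"sd of {name} ({label}) must be >= 0")
        for col, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{col!r}] must be >= 0")

    def with_noise_scale(self, scale: float) -> "CohortConfig":
        """Return a copy with every hemodynamic noise sd multiplied by `scale`."""
        return dataclasses.replace(
            self, noise_sd={k: v * scale for k, v in self.noise_sd.items()})

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Seeded generator for one named pipeline stage."""
        return np.random.default_rng(_stage_seed(self.seed, stage))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["diameters"] = {
            lab: {k: list(v) for k, v in params.items()}
            for lab, params in d["diameters"].items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "diameters" in d:
            d["diameters"] = {
                lab: {k: (float(v[0]), float(v[1])) for k, v in params.items()}
                for lab, params in d["diameters"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        """Stable short hash of the full configuration (provenance tag)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class LandmarkConfig:
    """Arc-length anchors for the nine diameter landmarks.

    Stations on the main vessel are located by fractional arc length except
    D1, which follows the literal anatomical rule "1 cm above the
    sinotubular junction" (the inlet), and D0/D4 which are found by
    minimisation/maximisation over the descending range.
    """

    d1_offset_mm: float = 10.0
    d2_fraction: float = 0.25
    d3_fraction: float = 0.55
    d5_fraction: float = 0.97
    descending_range: tuple[float, float] = (0.58, 0.92)
    branch_offset_mm: float = 2.0
    scan_step_mm: float = 0.5

    def validate(self) -> None:
        lo, hi = self.descending_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("descending_range must be an increasing pair in (0,1)")
        for name in ("d2_fraction", "d3_fraction", "d5_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0,1)")
        if self.scan_step_mm <= 0 or self.branch_offset_mm < 0:
            raise ValueError("scan_step_mm must be > 0, branch_offset_mm >= 0")


@dataclass
class RunConfig:
    """Full pipeline run configuration (cohort + modelling options)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    landmarks: LandmarkConfig = field(default_factory=LandmarkConfig)
    model_mode: str = "fitted"           # "fitted" | "published"
    standardize: bool = True
    threshold: float = 0.5
    test_fraction: float = 0.2
    all_features_ablation: bool = False
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.cohort.validate()
        self.landmarks.validate()
        if self.model_mode not in ("fitted", "published"):
            raise ValueError(f"model_mode must be fitted|published, got {self.model_mode!r}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0,1)")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0,1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["landmarks"]["descending_range"] = list(
            d["landmarks"]["descending_range"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "landmarks" in d and not isinstance(d["landmarks"], LandmarkConfig):
            lm = dict(d["landmarks"])
            if "descending_range" in lm:
                lm["descending_range"] = tuple(lm["descending_range"])
            d["landmarks"] = LandmarkConfig(**lm)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration and validate it."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)
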