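"""Tissue acoustic properties, their uncertainty model, and reproducible sampling.

The table holds, per tissue, the density rho (kg/m^3), speed of sound c (m/s)
and amplitude attenuation alpha (Np/m) entering the lossy wave equation,
together with the standard deviations of rho and c used as the uncertainty
model. Density and speed are treated as independent Gaussians truncated at
+/- 4 sigma (redraw on violation); attenuation is fixed. Water is the
background/coupling medium and is never perturbed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import TissueLookupError, UnsupportedPropertyError

__all__ = [
    "TissueAcousticProperties",
    "TissuePropertyDistribution",
    "TissueTable",
    "SampleSet",
    "default_tissue_table",
    "draw_samples",
    "child_seed",
    "DEFAULT_LABELS",
    "PRESET_SPEED8",
    "PRESET_SPEED_DENSITY16",
    "UNCERTAIN_TISSUES",
]

#: Canonical integer labels used by the phantom generator and property
#: assignment. Water is 0 so that zero-initialised volumes are valid.
DEFAULT_LABELS: dict[str, int] = {
    "water": 0,
    "skin": 1,
    "skull": 2,
    "csf": 3,
    "gray_matter": 4,
    "white_matter": 5,
    "cerebellum": 6,
    "ventricles": 7,
    "amygdala": 8,
}

#: The eight tissues whose properties carry uncertainty (water excluded).
UNCERTAIN_TISSUES: tuple[str, ...] = (
    "amygdala",
    "cerebellum",
    "csf",
    "gray_matter",
    "skull",
    "skin",
    "ventricles",
    "white_matter",
)

TRUNCATION_SIGMA = 4.0


@dataclass(frozen=True)
class TissueAcousticProperties:
    """Nominal (mean) acoustic properties of one tissue."""

    density: float  # kg/m^3
    speed_of_sound: float  # m/s
    attenuation: float  # Np/m

    def __post_init__(self) -> None:
        if self.density <= 0 or self.speed_of_sound <= 0:
            raise ValueError("density and speed of sound must be positive")
        if self.attenuation < 0:
            raise ValueError("attenuation must be non-negative")


@dataclass(frozen=True)
class TissuePropertyDistribution:
    """Mean/std of density and speed of sound; attenuation is fixed (std 0)."""

    density_mean: float
    density_std: float
    speed_mean: float
    speed_std: float
    attenuation: float

    def __post_init__(self) -> None:
        if self.density_std < 0 or self.speed_std < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.density_mean - TRUNCATION_SIGMA * self.density_std <= 0:
            raise ValueError("density mean - 4 sigma must stay positive")
        if self.speed_mean - TRUNCATION_SIGMA * self.speed_std <= 0:
            raise ValueError("speed mean - 4 sigma must stay positive")

    @property
    def nominal(self) -> TissueAcousticProperties:
        return TissueAcousticProperties(
            self.density_mean, self.speed_mean, self.attenuation
        )

    def mean_std(self, prop: str) -> tuple[float, float]:
        if prop == "density":
            return self.density_mean, self.density_std
        if prop == "speed_of_sound":
            return self.speed_mean, self.speed_std
        raise UnsupportedPropertyError(
            f"property {prop!r} has no uncertainty model (only density and "
            "speed_of_sound may be uncertain)"
        )


class TissueTable:
    """Mapping tissue name -> distribution, plus the integer label scheme."""

    def __init__(
        self,
        rows: Mapping[str, TissuePropertyDistribution],
        labels: Mapping[str, int] | None = None,
    ) -> None:
        self.rows = dict(rows)
        self.labels = dict(labels) if labels is not None else {
            name: DEFAULT_LABELS[name] for name in self.rows
        }
        missing = set(self.rows) - set(self.labels)
        if missing:
            raise ValueError(f"tissues without labels: {sorted(missing)}")

    def __getitem__(self, name: str) -> TissuePropertyDistribution:
        try:
            return self.rows[name]
        except KeyError:
            raise TissueLookupError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.rows

    def __iter__(self):
        return iter(self.rows)

    def nominal(self, name: str) -> TissueAcousticProperties:
        return self[name].nominal

    def name_of(self, label: int) -> str:
        for name, lab in self.labels.items():
            if lab == label:
                return name
        raise TissueLookupError(f"label {label}")

    @property
    def max_speed_bound(self) -> float:
        """Upper truncation bound on speed of sound over all tissues (m/s)."""
        return max(
            d.speed_mean + TRUNCATION_SIGMA * d.speed_std for d in self.rows.values()
        )

    # ---- persistence -----------------------------------------------------
    _CSV_COLUMNS = (
        "tissue",
        "density_mean",
        "density_std",
        "attenuation",
        "speed_mean",
        "speed_std",
    )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(self._CSV_COLUMNS)
            for name, d in self.rows.items():
                w.writerow(
                    [name, d.density_mean, d.density_std, d.attenuation,
                     d.speed_mean, d.speed_std]
                )

    @classmethod
    def from_csv(cls, path, labels: Mapping[str, int] | None = None) -> "TissueTable":
        rows: dict[str, TissuePropertyDistribution] = {}
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows[rec["tissue"]] = TissuePropertyDistribution(
                    float(rec["density_mean"]),
                    float(rec["density_std"]),
                    float(rec["speed_mean"]),
                    float(rec["speed_std"]),
                    float(rec["attenuation"]),
                )
        return cls(rows, labels)

    def to_yaml(self, path) -> None:
        import yaml

        data = {
            name: {
                "density_mean": d.density_mean,
                "density_std": d.density_std,
                "attenuation": d.attenuation,
                "speed_mean": d.speed_mean,
                "speed_std": d.speed_std,
            }
            for name, d in self.rows.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump({"tissues": data, "labels": self.labels}, fh)

    @classmethod
    def from_yaml(cls, path) -> "TissueTable":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        rows = {
            name: TissuePropertyDistribution(
                rec["density_mean"],
                rec["density_std"],
                rec["speed_mean"],
                rec["speed_std"],
                rec["attenuation"],
            )
            for name, rec in data["tissues"].items()
        }
        return cls(rows, data.get("labels"))


def default_tissue_table() -> TissueTable:
    """The nine-tissue acoustic property table (IT'IS-derived values).

    Density and speed of sound carry mean +/- std; attenuation is fixed.
    CSF and ventricles share identical values; water has zero attenuation
    and zero uncertainty.
    """
    rows = {
        "amygdala": TissuePropertyDistribution(1045.0, 7.0, 1552.5, 29.0, 0.22),
        "cerebellum": TissuePropertyDistribution(1045.0, 7.0, 1552.5, 29.0, 0.42),
        "csf": TissuePropertyDistribution(1007.0, 1.0, 1504.5, 3.5, 0.025),
        "gray_matter": TissuePropertyDistribution(1044.5, 8.0, 1552.5, 29.0, 0.22),
        "skull": TissuePropertyDistribution(1908.0, 166.0, 2813.7, 337.0, 13.63),
        "skin": TissuePropertyDistribution(1109.0, 38.0, 1624.0, 91.8, 5.29),
        "ventricles": TissuePropertyDistribution(1007.0, 1.0, 1504.5, 3.5, 0.025),
        "water": TissuePropertyDistribution(1000.0, 0.0, 1500.0, 0.0, 0.0),
        "white_matter": TissuePropertyDistribution(1041.0, 2.0, 1552.5, 29.0, 1.48),
    }
    return TissueTable(rows)


#: Speed of sound of the 8 non-water tissues uncertain (u = 8).
PRESET_SPEED8: tuple[tuple[str, str], ...] = tuple(
    (t, "speed_of_sound") for t in UNCERTAIN_TISSUES
)

#: Speed of sound plus density of the 8 non-water tissues (u = 16).
PRESET_SPEED_DENSITY16: tuple[tuple[str, str], ...] = PRESET_SPEED8 + tuple(
    (t, "density") for t in UNCERTAIN_TISSUES
)

_PRESETS = {
    "speed8": PRESET_SPEED8,
    "speed+density16": PRESET_SPEED_DENSITY16,
}


def resolve_preset(
    properties: str | Sequence[tuple[str, str]],
) -> tuple[tuple[str, str], ...]:
    if isinstance(properties, str):
        try:
            return _PRESETS[properties]
        except KeyError:
            raise UnsupportedPropertyError(
                f"unknown uncertainty preset {properties!r}; "
                f"known: {sorted(_PRESETS)}"
            ) from None
    return tuple((t, p) for t, p in properties)


@dataclass
class SampleSet:
    """Realised property values and their standardised (sigma-unit) form.

    ``values[k, j]`` is the realised value of ``index[j]`` in sample k;
    ``standardized[k, j] = (values[k, j] - means[j]) / stds[j]`` where the
    std is positive, and 0 for fixed (std = 0) columns.
    """

    values: np.ndarray  # (n_samples, u)
    standardized: np.ndarray  # (n_samples, u)
    index: tuple[tuple[str, str], ...]
    means: np.ndarray
    stds: np.ndarray
    seed: int

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def u(self) -> int:
        return self.values.shape[1]

    def row_overrides(self, k: int) -> dict[tuple[str, str], float]:
        """Property overrides {(tissue, property): value} for sample k."""
        return {key: float(self.values[k, j]) for j, key in enumerate(self.index)}

    def subset(self, rows: np.ndarray | slice) -> "SampleSet":
        return SampleSet(
            self.values[rows], self.standardized[rows], self.index,
            self.means, self.stds, self.seed,
        )


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from one master seed."""
    h = np.random.SeedSequence(
        master_seed, spawn_key=tuple(stage.encode())
    ).generate_state(1)[0]
    return int(h % (2**31 - 1))


def draw_samples(
    table: TissueTable,
    properties: str | Sequence[tuple[str, str]],
    n_samples: int,
    seed: int,
) -> SampleSet:
    """Draw truncated-normal property realisations.

    Each selected (tissue, property) column is drawn independently from
    Normal(mean, std) truncated to mean +/- 4 sigma (violations redrawn);
    std = 0 columns are constant at the mean. Identical seeds give bitwise
    identical sample sets.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    index = resolve_preset(properties)
    for tissue, prop in index:
        if prop not in ("density", "speed_of_sound"):
            raise UnsupportedPropertyError(
                f"cannot treat {prop!r} of {tissue!r} as uncertain"
            )
        table[tissue]  # raises TissueLookupError on unknown tissue

    means = np.array([table[t].mean_std(p)[0] for t, p in index])
    stds = np.array([table[t].mean_std(p)[1] for t, p in index])

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, len(index)))
    # redraw any |z| > 4 until within bounds (negligible distortion)
    bad = np.abs(z) > TRUNCATION_SIGMA
    while bad.any():
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(z) > TRUNCATION_SIGMA
    z[:, stds == 0] = 0.0
    values = means + stds * z
    return SampleSet(values, z, index, means, stds, int(seed))
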