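"""Run configuration.

Defaults mirror the acquisition and analysis settings of the study design
this pipeline implements: signals extracted between 3 and 11 minutes in an
m/z window of 360-442 with an area threshold of 5e5 counts; a d7-cholesterol
internal standard spiked at 5.08 nmol per sample; QC dilution correlation
threshold 0.75; 999 permutations for all permutation tests; NMDS accepted at
Kruskal stress <= 0.2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their study defaults.

    Attributes
    ----------
    rt_window : (float, float)
        Retention-time extraction window in minutes (inclusive).
    mz_window : (float, float)
        m/z extraction window in Da (inclusive).
    area_threshold : float
        Minimum signal area in counts (inclusive).
    is_moles : float
        Molar amount of internal standard per sample (mol).
    is_name : str
        Name of the internal-standard entry in the reference table.
    ppm_tolerance : float
        Accurate-mass matching tolerance in parts per million.
    rt_tolerance : float
        Retention-time matching window in minutes.
    qc_threshold : float
        Minimum Pearson correlation between QC nominal load and
        IS-normalised signal for a variable to be retained.
    blank_factor : float
        A feature is kept only if its median sample signal is at least
        this multiple of its median blank signal.
    outlier_threshold : float
        Minimum Bray-Curtis dissimilarity to every other sample for a
        sample to be flagged as an outlier.
    n_permutations : int
        Permutation count for PERMANOVA / IndVal / Blomberg-K p-values.
    nmds_max_tries : int
        Number of NMDS random restarts (a PCoA-seeded start is always
        attempted first).
    stress_cutoff : float
        Maximum acceptable Kruskal stress-1; dimensionality is escalated
        from k=2 while stress exceeds this.
    random_seed : int
        Seed for every stochastic stage.
    """

    rt_window: tuple[float, float] = (3.0, 11.0)
    mz_window: tuple[float, float] = (360.0, 442.0)
    area_threshold: float = 500_000.0
    is_moles: float = 5.08e-9
    is_name: str = "d7-cholesterol"
    ppm_tolerance: float = 3.0
    rt_tolerance: float = 0.1
    qc_threshold: float = 0.75
    blank_factor: float = 3.0
    outlier_threshold: float = 0.5
    n_permutations: int = 999
    nmds_max_tries: int = 200
    stress_cutoff: float = 0.2
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.rt_window
        if not lo < hi:
            raise ConfigError(f"rt_window must be non-empty, got {self.rt_window}")
        lo, hi = self.mz_window
        if not lo < hi:
            raise ConfigError(f"mz_window must be non-empty, got {self.mz_window}")
        for name in ("ppm_tolerance", "rt_tolerance", "is_moles", "blank_factor"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.area_threshold < 0:
            raise ConfigError("area_threshold must be >= 0")
        if self.n_permutations < 1:
            raise ConfigError(
                f"n_permutations must be >= 1, got {self.n_permutations}"
            )
        if self.nmds_max_tries < 1:
            raise ConfigError("nmds_max_tries must be >= 1")
        if not 0 < self.stress_cutoff:
            raise ConfigError("stress_cutoff must be > 0")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rt_window"] = list(self.rt_window)
        d["mz_window"] = list(self.mz_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("rt_window", "mz_window"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
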