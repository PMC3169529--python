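"""Domain types shared across the pipeline.

A twin cohort is described by a :class:`CohortDesign` (how many MZ/DZ pairs,
how many clinic visits, how many technical-replicate aliquots per sample) and
materialised as a *metadata table*: one row per aliquot record with columns

    record_id, subject_id, pair_id, zygosity, twin_index, visit, aliquot,
    plate, time, age, sex

``zygosity`` is ``"MZ"``, ``"DZ"`` or ``"NA"`` (singleton).  ``time`` is the
sample-collection clock hour (the cohorts mostly collected at 10:00 or 14:00).
The (pair_id, twin_index) pair uniquely identifies a subject, and co-twins
share every visit index because twins attend the clinic in pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

META_COLUMNS = [
    "record_id", "subject_id", "pair_id", "zygosity", "twin_index",
    "visit", "aliquot", "plate", "time",
]


class DesignError(ValueError):
    """Raised for invalid cohort designs or model specifications."""


@dataclass
class CohortDesign:
    """Sampling design of a longitudinal twin cohort.

    ``visits_per_pair`` may be a single count applied to every pair-like unit
    (MZ pair, DZ pair, or singleton), or a sequence giving the visit count of
    each unit in order (MZ pairs first, then DZ pairs, then singletons).
    """

    n_mz_pairs: int
    n_dz_pairs: int
    n_singletons: int = 0
    visits_per_pair: int | Sequence[int] = 1
    aliquots_per_sample: int = 1
    plates: int = 1
    visit_times: Sequence[float] = (10.0, 14.0)

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_singletons"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.aliquots_per_sample < 1:
            raise DesignError("aliquots_per_sample must be >= 1")
        if self.plates < 1:
            raise DesignError("plates must be >= 1")
        if len(tuple(self.visit_times)) == 0:
            raise DesignError("visit_times must be nonempty")
        n_units = self.n_mz_pairs + self.n_dz_pairs + self.n_singletons
        if not np.isscalar(self.visits_per_pair):
            if len(self.visits_per_pair) != n_units:
                raise DesignError(
                    "per-unit visits_per_pair must have one entry per "
                    f"MZ pair, DZ pair and singleton ({n_units} units)"
                )
            if any(v < 0 for v in self.visits_per_pair):
                raise DesignError("visit counts must be >= 0")
        elif self.visits_per_pair < 0:
            raise DesignError("visits_per_pair must be >= 0")

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_mz_pairs + 2 * self.n_dz_pairs + self.n_singletons

    def unit_visits(self) -> list[int]:
        """Visit count for each pair-like unit, MZ pairs first."""
        n_units = self.n_mz_pairs + self.n_dz_pairs + self.n_singletons
        if np.isscalar(self.visits_per_pair):
            return [int(self.visits_per_pair)] * n_units
        return [int(v) for v in self.visits_per_pair]


def moltwin_design() -> CohortDesign:
    """The discovery cohort's design: 51 MZ pairs (33 of which donated
    samples at two visits), 19 DZ pairs, 2 singletons, two technical-replicate
    aliquots per biological sample."""
    visits = [2] * 33 + [1] * 18 + [1] * 19 + [1] * 2
    return CohortDesign(
        n_mz_pairs=51, n_dz_pairs=19, n_singletons=2,
        visits_per_pair=visits, aliquots_per_sample=2, plates=5,
        visit_times=(10.0, 14.0),
    )


@dataclass
class VCParams:
    """Parameters of the twin variance-components phenotype model.

    The phenotype of aliquot l, visit k, twin j in pair i is

        y_ijkl = beta0 + beta_g * g_ij + plate effect + beta_time * time
                 + f_ij + e_ij + v_ik (common visit) + w_ijk (individual
                 visit) + eps_ijkl

    with every random term zero-mean Gaussian at its standard deviation.  The
    familial effect f is shared by MZ co-twins and correlated
    ``dz_familial_corr`` between DZ co-twins; it pools genetic and
    common-environment influences, which a twin design cannot separate.
    """

    beta0: float = 0.0
    beta_g: float = 0.0
    plate_effects: Sequence[float] | None = None
    beta_time: float = 0.0
    sigma_f: float = 0.0
    sigma_e: float = 0.0
    sigma_vc: float = 0.0
    sigma_vi: float = 0.0
    sigma_eps: float = 0.0
    dz_familial_corr: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sigma_f", "sigma_e", "sigma_vc", "sigma_vi", "sigma_eps"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if not 0.0 <= self.dz_familial_corr <= 1.0:
            raise DesignError("dz_familial_corr must be in [0, 1]")

    def sds(self) -> np.ndarray:
        return np.array([self.sigma_f, self.sigma_e, self.sigma_vc,
                         self.sigma_vi, self.sigma_eps])


@dataclass
class PeakCatalog:
    """Catalog of synthetic metabolite resonances and their extraction bins.

    Each peak has a Lorentzian line centred at ``center`` ppm with the given
    half-width at half-maximum, an intensity scale factor (protons per
    molecule), and a closed ppm bin from which its height is read back.
    """

    names: Sequence[str]
    centers: Sequence[float]
    half_widths: Sequence[float]
    scales: Sequence[float]
    bins: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        n = len(self.names)
        for fld in ("centers", "half_widths", "scales", "bins"):
            if len(getattr(self, fld)) != n:
                raise DesignError(f"catalog field {fld} length != {n}")
        for lo, hi in self.bins:
            if not lo < hi:
                raise DesignError("bin intervals must be non-degenerate")
        if any(h <= 0 for h in self.half_widths):
            raise DesignError("half-widths must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "peak": list(self.names),
            "center": list(self.centers),
            "half_width": list(self.half_widths),
            "scale": list(self.scales),
            "bin_lo": [b[0] for b in self.bins],
            "bin_hi": [b[1] for b in self.bins],
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeakCatalog":
        return cls(
            names=list(df["peak"]),
            centers=list(df["center"]),
            half_widths=list(df["half_width"]),
            scales=list(df["scale"]),
            bins=list(zip(df["bin_lo"], df["bin_hi"])),
        )


@dataclass
class InterfererSpec:
    """Occasional overlapping resonance used to create censored missingness:
    with probability ``probability`` per spectrum, a large Lorentzian at
    ``center`` swamps any bin it overlaps."""

    center: float
    half_width: float
    amplitude: float
    probability: float = 0.1


@dataclass
class SpectrumSet:
    """A ppm axis plus one intensity column per aliquot record."""

    ppm: np.ndarray
    intensities: pd.DataFrame  # index aligned to ppm, columns = record ids

    def __post_init__(self) -> None:
        if len(self.ppm) != len(self.intensities):
            raise DesignError("ppm axis and intensity table length mismatch")

    def spectrum(self, record_id: str) -> "Spectrum":
        return Spectrum(self.ppm.copy(),
                        self.intensities[record_id].to_numpy(copy=True),
                        record_id)

    @property
    def record_ids(self) -> list[str]:
        return list(self.intensities.columns)


@dataclass
class Spectrum:
    """A single 1D NMR spectrum: strictly monotone ppm axis + intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    record_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise DesignError("ppm and intensity must have equal length")
        d = np.diff(self.ppm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise DesignError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise DesignError("intensities must be finite")
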