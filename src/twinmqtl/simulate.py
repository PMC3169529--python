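"""Synthetic twin-cohort generator.

Produces every input the downstream pipeline needs without real data:

* a cohort metadata table of MZ/DZ twin pairs plus singletons, with
  longitudinal visits, duplicate aliquots, and randomized plate allocation;
* Hardy–Weinberg genotypes in which MZ co-twins are genetically identical and
  DZ co-twins are generated by explicit two-parent transmission (so
  identity-by-descent sharing, and hence the expected within-pair dosage
  correlation of 1/2, is genuine rather than imposed);
* phenotypes drawn from the twin variance-components model (additive SNP
  effect, plate and collection-time fixed effects, familial /
  individual-environment / common-visit / individual-visit / experimental
  random effects);
* spectra as sums of Lorentzian resonances with a two-sided constant
  baseline, additive Gaussian noise, small chemical-shift jitter, and
  optional interfering resonances that censor neighbouring bins.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    CohortDesign, DesignError, InterfererSpec, PeakCatalog, SpectrumSet,
    VCParams, META_COLUMNS,
)
from .genotypes import GenotypeMatrix


def simulate_cohort(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Materialise a cohort design as a metadata table (one row per aliquot).

    Subjects are named ``S####``; pairs ``P###``; records
    ``<subject>_v<visit>_a<aliquot>``.  Plates are allocated to records by a
    seeded random permutation (a randomized plate design).  Collection times
    alternate between the design's clock hours per visit, shared by co-twins
    (twins visit the clinic together).
    """
    rng = np.random.default_rng(seed)
    units: list[tuple[str, str, int]] = []  # (zygosity, pair_id, n_subjects)
    for i in range(design.n_mz_pairs):
        units.append(("MZ", f"P{i + 1:03d}", 2))
    for i in range(design.n_dz_pairs):
        units.append(("DZ", f"P{design.n_mz_pairs + i + 1:03d}", 2))
    for i in range(design.n_singletons):
        units.append(("NA", f"U{i + 1:03d}", 1))
    unit_visits = design.unit_visits()
    times = list(design.visit_times)

    rows = []
    subj_counter = 0
    for (zyg, pair_id, n_subj), n_visits in zip(units, unit_visits):
        subj_ids = []
        for t in range(n_subj):
            subj_counter += 1
            subj_ids.append(f"S{subj_counter:04d}")
        visit_times = [times[rng.integers(len(times))] for _ in range(n_visits)]
        for twin_index, subj in enumerate(subj_ids, start=1):
            for k in range(1, n_visits + 1):
                for a in range(1, design.aliquots_per_sample + 1):
                    rows.append({
                        "record_id": f"{subj}_v{k}_a{a}",
                        "subject_id": subj,
                        "pair_id": pair_id,
                        "zygosity": zyg,
                        "twin_index": twin_index if n_subj == 2 else 1,
                        "visit": k,
                        "aliquot": a,
                        "plate": -1,
                        "time": visit_times[k - 1],
                    })
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    if len(meta):
        # randomized plate design: records spread over plates by permutation
        plate_cycle = np.resize(np.arange(design.plates) + 1, len(meta))
        meta["plate"] = plate_cycle[rng.permutation(len(meta))]
    return meta


def _hwe_dosages(rng: np.random.Generator, n: int, p: np.ndarray) -> np.ndarray:
    """n independent HWE dosages at reference-allele frequencies p (per SNP)."""
    return (rng.random((n, p.size)) < p).astype(np.int64) + (
        rng.random((n, p.size)) < p
    ).astype(np.int64)


def simulate_genotypes(
    meta: pd.DataFrame,
    n_snps: int,
    maf: float | tuple[float, float] | Sequence[float] = 0.3,
    seed: int = 0,
    chrom: int = 1,
) -> GenotypeMatrix:
    """Simulate genome-wide dosages for every subject in ``meta``.

    MZ co-twins receive identical rows.  DZ co-twins are produced by drawing
    two HWE parents and transmitting one allele from each to each twin, which
    induces the familiar 1/2 expected dosage correlation.  Singletons are
    independent HWE draws.

    ``maf`` may be a single frequency, a ``(low, high)`` tuple giving a range
    sampled uniformly per SNP, or a per-SNP sequence (list/array).
    Frequencies must lie in (0, 0.5].
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(maf):
        p = np.full(n_snps, float(maf))
    elif isinstance(maf, tuple) and len(maf) == 2:
        p = rng.uniform(float(maf[0]), float(maf[1]), size=n_snps)
    else:
        p = np.asarray(maf, dtype=float)
        if p.size != n_snps:
            raise DesignError("per-SNP maf length must equal n_snps")
    if np.any(p <= 0) or np.any(p > 0.5):
        raise DesignError("MAFs must lie in (0, 0.5]")

    subjects = meta.drop_duplicates("subject_id")[
        ["subject_id", "pair_id", "zygosity", "twin_index"]
    ].reset_index(drop=True)
    n_subj = len(subjects)
    dosage = np.zeros((n_subj, n_snps), dtype=np.int64)

    by_pair = subjects.groupby("pair_id", sort=False)
    for pair_id, grp in by_pair:
        idx = grp.index.to_numpy()
        zyg = grp["zygosity"].iloc[0]
        if zyg == "MZ" and len(idx) == 2:
            g = _hwe_dosages(rng, 1, p)
            dosage[idx[0]] = g
            dosage[idx[1]] = g
        elif zyg == "DZ" and len(idx) == 2:
            # two parents, each transmitting one uniformly chosen allele
            mother = np.stack([(rng.random(n_snps) < p).astype(np.int64)
                               for _ in range(2)])
            father = np.stack([(rng.random(n_snps) < p).astype(np.int64)
                               for _ in range(2)])
            for j in idx:
                mi = rng.integers(2, size=n_snps)
                fi = rng.integers(2, size=n_snps)
                dosage[j] = (mother[mi, np.arange(n_snps)]
                             + father[fi, np.arange(n_snps)])
        else:
            for j in idx:
                dosage[j] = _hwe_dosages(rng, 1, p)

    snp_ids = [f"snp{j + 1:05d}" for j in range(n_snps)]
    dosages = pd.DataFrame(dosage, index=subjects["subject_id"].to_numpy(),
                           columns=snp_ids)
    snps = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(1, n_snps + 1) * 1000,
        "ref": "A",
        "alt": "G",
        "maf_design": p,
    }, index=pd.Index(snp_ids, name="snp"))
    return GenotypeMatrix(dosages, snps)


def simulate_phenotypes(
    meta: pd.DataFrame,
    dosage: Mapping[str, float] | pd.Series,
    params: VCParams,
    seed: int = 0,
) -> pd.Series:
    """Draw one phenotype per aliquot record from the variance-components
    model (log-concentration scale).

    ``dosage`` maps subject_id -> dosage at the causal SNP.  Raises if any
    subject in ``meta`` lacks a genotype.
    """
    rng = np.random.default_rng(seed)
    dosage = pd.Series(dosage)
    missing = set(meta["subject_id"]) - set(dosage.index)
    if missing:
        raise DesignError(f"missing genotype for subjects: {sorted(missing)[:5]}")

    n = len(meta)
    g = dosage.loc[meta["subject_id"]].to_numpy(dtype=float)
    y = params.beta0 + params.beta_g * g + params.beta_time * meta["time"].to_numpy()
    if params.plate_effects is not None:
        pe = np.asarray(params.plate_effects, dtype=float)
        y = y + pe[meta["plate"].to_numpy() - 1]

    # familial effects: shared within MZ pairs, correlated within DZ pairs
    fam = {}
    rho = params.dz_familial_corr
    for pair_id, grp in meta.drop_duplicates("subject_id").groupby(
            "pair_id", sort=False):
        subs = grp["subject_id"].tolist()
        zyg = grp["zygosity"].iloc[0]
        if zyg == "MZ" and len(subs) == 2:
            f = rng.normal(0.0, params.sigma_f)
            fam[subs[0]] = fam[subs[1]] = f
        elif zyg == "DZ" and len(subs) == 2:
            z1, z2 = rng.normal(size=2)
            fam[subs[0]] = params.sigma_f * z1
            fam[subs[1]] = params.sigma_f * (rho * z1 + np.sqrt(1 - rho ** 2) * z2)
        else:
            for s in subs:
                fam[s] = rng.normal(0.0, params.sigma_f)

    env = {s: rng.normal(0.0, params.sigma_e)
           for s in meta["subject_id"].unique()}
    vc = {pv: rng.normal(0.0, params.sigma_vc)
          for pv in meta[["pair_id", "visit"]].drop_duplicates().itertuples(
              index=False, name=None)}
    vi = {sv: rng.normal(0.0, params.sigma_vi)
          for sv in meta[["subject_id", "visit"]].drop_duplicates().itertuples(
              index=False, name=None)}

    y = (
        y
        + meta["subject_id"].map(fam).to_numpy()
        + meta["subject_id"].map(env).to_numpy()
        + np.array([vc[(p, k)] for p, k in
                    zip(meta["pair_id"], meta["visit"])])
        + np.array([vi[(s, k)] for s, k in
                    zip(meta["subject_id"], meta["visit"])])
        + rng.normal(0.0, params.sigma_eps, size=n)
    )
    return pd.Series(y, index=pd.Index(meta["record_id"], name="record_id"),
                     name="y")


def default_ppm_axis(lo: float = 0.0, hi: float = 10.0,
                     n_points: int = 4096) -> np.ndarray:
    return np.linspace(lo, hi, n_points)


def lorentzian(ppm: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Unit-apex Lorentzian lineshape."""
    return half_width ** 2 / ((ppm - center) ** 2 + half_width ** 2)


def simulate_spectra(
    catalog: PeakCatalog,
    concentrations: pd.DataFrame,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    ppm_jitter_sd: float = 0.0,
    interferers: Sequence[InterfererSpec] = (),
    seed: int = 0,
    ppm: np.ndarray | None = None,
    water_interval: tuple[float, float] = (4.5, 5.0),
) -> SpectrumSet:
    """Render spectra from a samples × peaks concentration matrix.

    Each spectrum is the sum over catalog peaks of
    ``concentration * scale * Lorentzian(center + jitter, half_width)``, plus
    a piecewise-constant baseline (independent constant on either side of the
    water interval), optional interferer resonances, and iid Gaussian noise.
    """
    if (np.asarray(concentrations) < 0).any():
        raise DesignError("concentrations must be >= 0")
    missing = set(catalog.names) - set(concentrations.columns)
    if missing:
        raise DesignError(f"concentrations lack catalog peaks: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    if ppm is None:
        ppm = default_ppm_axis()
    b_left, b_right = baseline
    base = np.where(ppm < water_interval[0], b_left,
                    np.where(ppm > water_interval[1], b_right,
                             0.5 * (b_left + b_right)))
    cols = {}
    for rec in concentrations.index:
        spec = base.copy()
        for name, c, hw, sc in zip(catalog.names, catalog.centers,
                                   catalog.half_widths, catalog.scales):
            conc = float(concentrations.loc[rec, name])
            jitter = rng.normal(0.0, ppm_jitter_sd) if ppm_jitter_sd > 0 else 0.0
            if conc > 0:
                spec = spec + conc * sc * lorentzian(ppm, c + jitter, hw)
        for itf in interferers:
            if rng.random() < itf.probability:
                spec = spec + itf.amplitude * lorentzian(
                    ppm, itf.center, itf.half_width)
        if noise_sd > 0:
            spec = spec + rng.normal(0.0, noise_sd, size=ppm.size)
        cols[str(rec)] = spec
    return SpectrumSet(ppm, pd.DataFrame(cols, index=np.arange(ppm.size)))
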