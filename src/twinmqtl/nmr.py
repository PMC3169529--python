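"""Spectral preprocessing: from aligned 1D spectra to a normalized,
log-transformed peak-height table.

The stages mirror a standard urine/plasma NMR workflow: reference alignment
(to TSP at δ0.00 for urine, formate at δ8.452 for plasma), wavelet
denoising, a two-piece piecewise-constant baseline (the 5th percentile of
each side of the water region, a robust location estimate), peak-height
extraction from fixed ppm bins (height proxies area; a bin with no interior
local maximum yields a missing value), an 80%-presence filter, probabilistic
quotient normalization against a median reference profile, and a global
affine rescale to [0, 100] followed by a log2(x + 1) transform.

Peak tables are DataFrames with one row per aliquot record, one column per
bin, and NaN marking missing heights.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pywt

from .design import PeakCatalog, Spectrum, SpectrumSet

MISSING = float("nan")


class PreprocessError(ValueError):
    pass


class AlignmentError(PreprocessError):
    pass


# ---------------------------------------------------------------------------
# local maxima
# ---------------------------------------------------------------------------

def _local_maxima(y: np.ndarray) -> list[tuple[float, float]]:
    """Interior local maxima of a vector as (fractional index, height).

    A strict interior point greater than both neighbours is a maximum; a
    maximal flat run strictly above both of its neighbours counts as one
    maximum located at the run's midpoint.  Runs touching either end are not
    interior and are ignored.
    """
    n = len(y)
    if n < 3:
        return []
    out = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        # flat run [i, j]; interior iff it does not touch the ends
        if j < n - 1 and y[i - 1] < y[i] and y[j + 1] < y[i]:
            out.append(((i + j) / 2.0, float(y[i])))
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# per-spectrum stages
# ---------------------------------------------------------------------------

def align_to_reference(s: Spectrum, ref_ppm: float,
                       search_window: tuple[float, float]) -> Spectrum:
    """Shift the ppm axis so the highest local maximum inside
    ``search_window`` sits exactly at ``ref_ppm``."""
    lo, hi = sorted(search_window)
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise AlignmentError("search window contains no axis points")
    seg = s.intensity[idx[0]:idx[-1] + 1]
    maxima = _local_maxima(seg)
    if not maxima:
        raise AlignmentError("no local maximum in the reference window")
    frac_idx, _ = max(maxima, key=lambda m: m[1])
    base = idx[0]
    i0 = int(np.floor(frac_idx))
    frac = frac_idx - i0
    apex_ppm = (1 - frac) * s.ppm[base + i0] + frac * s.ppm[
        min(base + i0 + 1, len(s.ppm) - 1)]
    shift = ref_ppm - apex_ppm
    return Spectrum(s.ppm + shift, s.intensity.copy(), s.record_id)


def denoise(s: Spectrum, wavelet: str = "sym8", level: int | None = None,
            mode: str = "symmetric") -> Spectrum:
    """Wavelet shrinkage with the universal soft threshold.

    The noise scale is estimated from the finest detail coefficients by the
    median absolute deviation; detail coefficients are soft-thresholded at
    sigma * sqrt(2 log n).  Degenerate inputs (too short, or no detail
    energy) pass through unchanged.
    """
    y = s.intensity
    n = len(y)
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if max_level < 1:
        return Spectrum(s.ppm.copy(), y.copy(), s.record_id)
    if level is None or level > max_level:
        level = max_level
    coeffs = pywt.wavedec(y, wavelet, mode=mode, level=level)
    d1 = coeffs[-1]
    sigma = np.median(np.abs(d1 - np.median(d1))) / 0.6744897501960817
    if sigma == 0:
        return Spectrum(s.ppm.copy(), y.copy(), s.record_id)
    thresh = sigma * np.sqrt(2.0 * np.log(n))
    new = [coeffs[0]] + [pywt.threshold(c, thresh, mode="soft")
                         for c in coeffs[1:]]
    rec = pywt.waverec(new, wavelet, mode=mode)[:n]
    return Spectrum(s.ppm.copy(), rec, s.record_id)


def baseline_two_piece(s: Spectrum, water_interval: tuple[float, float],
                       percentile: float = 5.0) -> Spectrum:
    """Subtract a piecewise-constant baseline, estimated independently on
    each side of the water interval as that side's empirical percentile
    (linear-interpolation definition).  Points inside the water interval are
    excluded from both estimates and get the nearer side's offset."""
    lo, hi = sorted(water_interval)
    left = s.ppm < lo
    right = s.ppm > hi
    if not left.any() or not right.any():
        raise PreprocessError(
            "water interval must leave axis points on both sides")
    off_left = np.percentile(s.intensity[left], percentile)
    off_right = np.percentile(s.intensity[right], percentile)
    mid = 0.5 * (lo + hi)
    offsets = np.where(s.ppm < lo, off_left,
                       np.where(s.ppm > hi, off_right,
                                np.where(s.ppm <= mid, off_left, off_right)))
    return Spectrum(s.ppm.copy(), s.intensity - offsets, s.record_id)


def extract_peak_height(s: Spectrum, bin_interval: tuple[float, float]) -> float:
    """Height of the highest interior local maximum inside a closed ppm bin,
    or NaN when no interior local maximum exists (missing value)."""
    lo, hi = sorted(bin_interval)
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if not mask.any():
        raise PreprocessError(f"bin ({lo}, {hi}) contains no axis points")
    idx = np.nonzero(mask)[0]
    seg = s.intensity[idx[0]:idx[-1] + 1]
    maxima = _local_maxima(seg)
    if not maxima:
        return MISSING
    return max(h for _, h in maxima)


# ---------------------------------------------------------------------------
# table stages
# ---------------------------------------------------------------------------

def extract_peak_table(spectra: SpectrumSet, catalog: PeakCatalog) -> pd.DataFrame:
    """Peak heights for every (record, bin) in one table (rows = records)."""
    rows = {}
    for rec in spectra.record_ids:
        s = spectra.spectrum(rec)
        rows[rec] = [extract_peak_height(s, b) for b in catalog.bins]
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(catalog.names))
    table.index.name = "record_id"
    return table


def presence_fraction(table: pd.DataFrame) -> pd.Series:
    return table.notna().mean(axis=0)


def filter_common_peaks(table: pd.DataFrame,
                        min_presence: float = 0.80) -> pd.DataFrame:
    """Keep peaks present in at least ``min_presence`` of records (boundary
    inclusive)."""
    keep = presence_fraction(table) >= min_presence
    return table.loc[:, keep]


def drop_excluded_peaks(
    table: pd.DataFrame,
    exclusion: Iterable[str] = (),
    redundant_groups: Sequence[tuple[Sequence[str], str]] = (),
) -> pd.DataFrame:
    """Remove excluded peak columns (e.g. spike-in references, urea,
    exogenous compounds) and collapse each redundant group — peaks annotated
    to the same metabolite — to its designated representative column."""
    exclusion = list(exclusion)
    missing = set(exclusion) - set(table.columns)
    if missing:
        raise PreprocessError(f"exclusion names unknown columns: {sorted(missing)}")
    drop = set(exclusion)
    for members, representative in redundant_groups:
        members = list(members)
        if representative not in members:
            raise PreprocessError(
                f"representative {representative!r} not in its group")
        drop.update(set(members) - {representative})
    return table.loc[:, [c for c in table.columns if c not in drop]]


def pqn_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Probabilistic quotient normalization.

    The reference profile is the per-peak median over non-missing heights;
    each record's dilution factor is the median over its non-missing peaks of
    (height / reference height); the record's row is divided by its factor.
    Missing cells stay missing.  Returns (normalized table, factors).
    """
    if len(table) < 2:
        raise PreprocessError("PQN needs at least 2 records")
    all_missing = table.isna().all(axis=1)
    if all_missing.any():
        bad = table.index[all_missing][0]
        raise PreprocessError(f"record {bad!r} has no non-missing peaks")
    reference = table.median(axis=0, skipna=True)
    quotients = table.div(reference, axis=1)
    factors = quotients.median(axis=1, skipna=True)
    return table.div(factors, axis=0), factors.rename("pqn_factor")


def log_transform_table(table: pd.DataFrame, offset: float = 1.0,
                        base: float = 2.0) -> pd.DataFrame:
    """Affinely map the table-wide range onto [0, 100], then apply
    log(x + offset) cellwise (base 2 by default).  Missing preserved."""
    vals = table.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size < 2 or finite.min() == finite.max():
        raise PreprocessError("table must contain >= 2 distinct finite values")
    lo, hi = finite.min(), finite.max()
    scaled = (table - lo) * (100.0 / (hi - lo))
    return np.log(scaled + offset) / np.log(base)


def preprocess_spectra(
    spectra: SpectrumSet,
    catalog: PeakCatalog,
    water_interval: tuple[float, float] = (4.5, 5.0),
    baseline_percentile: float = 5.0,
    min_presence: float = 0.80,
    log_offset: float = 1.0,
    denoise_spectra: bool = False,
    align: tuple[float, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Full stack: (align) → (denoise) → baseline → extract → presence
    filter → PQN → log transform.  Returns (peak table, PQN factors)."""
    processed = {}
    for rec in spectra.record_ids:
        s = spectra.spectrum(rec)
        if align is not None:
            s = align_to_reference(s, align[0], align[1])
        if denoise_spectra:
            s = denoise(s)
        s = baseline_two_piece(s, water_interval, baseline_percentile)
        processed[rec] = s
    table = pd.DataFrame.from_dict(
        {rec: [extract_peak_height(s, b) for b in catalog.bins]
         for rec, s in processed.items()},
        orient="index", columns=list(catalog.names))
    table.index.name = "record_id"
    table = filter_common_peaks(table, min_presence)
    table, factors = pqn_normalize(table)
    return log_transform_table(table, offset=log_offset), factors


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_peak_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA", index_label="record_id")


def read_peak_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="record_id",
                       na_values="NA", comment="#")


def write_spectra(spectra: SpectrumSet, path) -> None:
    df = spectra.intensities.copy()
    df.insert(0, "ppm", spectra.ppm)
    df.to_csv(path, sep="\t", index=False)


def read_spectra(path) -> SpectrumSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    ppm = df.pop("ppm").to_numpy()
    return SpectrumSet(ppm, df.reset_index(drop=True))
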