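"""Torsion-angle deviation statistics against reference geometries.

For each tracked backbone angle, the per-frame circular deviation from a
reference (DFT-optimized) value is histogrammed, the deviation
distribution is modeled as a sum of Gaussian peaks, and the peak nearest
d = 0 is summarized by its mean and width.  A Z-score — the distance of
the reference from the nearest simulated mode, in mode widths — and the
associated two-sided normal tail probability quantify how significantly
the ensemble deviates from the reference.  Reports: a |mu| > 30 deg
outlier table and a comparison of the implied ensemble-mean angles with
the ideal turn angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import ndtr

from .dihedrals import circular_difference, wrap_angle
from .reference_data import get_ideal_angles

__all__ = [
    "DeviationHistogram",
    "GaussianPeak",
    "ZScoreResult",
    "deviation_series",
    "histogram_deviations",
    "fit_nearest_peak",
    "zscore",
    "outlier_table",
    "ideal_comparison_table",
    "compare_to_reference",
    "ANGLE_POSITIONS",
]

#: the four turn residues, in table order
ANGLE_POSITIONS = ("i", "i+1", "i+2", "i+3")

MIN_DEVIATIONS = 50
MAX_PEAKS = 5
SIGMA_BOUNDS = (1.0, 120.0)
#: local maxima (and fitted components) below this fraction of the tallest
#: one are treated as count noise, not modes
RELATIVE_PEAK_FLOOR = 0.02


@dataclass
class DeviationHistogram:
    bin_edges: np.ndarray  # degrees, covering (-180, 180]
    counts: np.ndarray
    n: int  # number of defined deviations

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def density(self) -> np.ndarray:
        return self.counts / (self.n * self.width)


@dataclass
class GaussianPeak:
    """Fitted Gaussian component nearest the reference (d = 0)."""

    mu: float  # degrees, in (-180, 180]
    sigma: float  # degrees, > 0
    amplitude: float  # density height
    rss: float
    n_peaks_fitted: int


@dataclass
class ZScoreResult:
    z: float
    probability: float  # two-sided normal tail probability in (0, 1]


def deviation_series(torsion_series, residue_id, which, reference_value,
                     frames=None) -> np.ndarray:
    """Per-frame wrapped deviation (MD angle - reference), degrees.

    ``frames`` optionally restricts the series to a subset (e.g. the
    members of a dPCA cluster); order is preserved.  Undefined frames
    are dropped.
    """
    if reference_value is None or np.isnan(reference_value):
        raise ValueError("reference value is undefined")
    series = torsion_series.column(residue_id, which)
    if frames is not None:
        series = series[np.asarray(frames, dtype=int)]
    series = series[~np.isnan(series)]
    if series.size == 0:
        raise ValueError(f"{which} of residue {residue_id} is undefined in all frames")
    return circular_difference(series, reference_value)


def histogram_deviations(deviations, bin_width: float = 5.0) -> DeviationHistogram:
    """Histogram deviations on a fixed grid over (-180, 180]."""
    if 360.0 % bin_width != 0:
        raise ValueError("bin width must divide 360")
    deviations = np.asarray(deviations, dtype=float)
    deviations = deviations[~np.isnan(deviations)]
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    # (-180, 180] binning: values equal to an edge belong to the bin below
    counts, _ = np.histogram(np.nextafter(deviations, -np.inf), bins=edges)
    return DeviationHistogram(bin_edges=edges, counts=counts, n=int(deviations.size))


def _circular_smooth(y: np.ndarray) -> np.ndarray:
    return (np.roll(y, 1) + y + np.roll(y, -1)) / 3.0


def _find_peaks(centers, smoothed):
    left = np.roll(smoothed, 1)
    right = np.roll(smoothed, -1)
    floor = RELATIVE_PEAK_FLOOR * smoothed.max()
    is_max = (smoothed > left) & (smoothed >= right) & (smoothed > floor)
    idx = np.nonzero(is_max)[0]
    order = np.argsort(smoothed[idx])[::-1]
    return idx[order][:MAX_PEAKS]


def _wrapped_gaussian_model(x, *params):
    y = np.zeros_like(x)
    for j in range(len(params) // 3):
        amp, mu, sigma = params[3 * j: 3 * j + 3]
        for k in (-360.0, 0.0, 360.0):
            y = y + amp * np.exp(-0.5 * ((x - mu + k) / sigma) ** 2)
    return y


def fit_nearest_peak(histogram, deviations=None) -> GaussianPeak:
    """Fit a sum of Gaussians to a deviation histogram; return the peak
    nearest d = 0.

    Local maxima of the 3-bin-smoothed density seed one Gaussian each
    (at most five, tallest first); all components are then fitted
    jointly by nonlinear least squares on the binned density with a
    circularly wrapped Gaussian model (each component summed over its
    +-360 deg images), sigma bounded to [1, 120] deg.  The returned
    component is the one whose fitted mean is circularly closest to
    zero; an exact tie is broken toward the negative mean.
    """
    if deviations is not None:
        histogram = histogram_deviations(deviations) if histogram is None else histogram
    if histogram.n < MIN_DEVIATIONS:
        raise ValueError(
            f"need at least {MIN_DEVIATIONS} defined deviations, have {histogram.n}"
        )
    centers = histogram.centers
    density = histogram.density
    smoothed = _circular_smooth(density)
    peak_idx = _find_peaks(centers, smoothed)
    if peak_idx.size == 0:
        raise ValueError("no peak: deviation histogram is flat")

    width = histogram.width
    n_bins = centers.size
    p0, lower, upper = [], [], []
    for i in peak_idx:
        h = smoothed[i]
        # half-width at half maximum, walked circularly
        steps = 1
        for direction in (1, -1):
            s = 1
            while s < n_bins // 2 and smoothed[(i + direction * s) % n_bins] > h / 2:
                s += 1
            steps = max(steps, s)
        sigma0 = float(np.clip(steps * width / 1.177, *SIGMA_BOUNDS))
        p0 += [float(density[i]), float(centers[i]), sigma0]
        lower += [0.0, float(centers[i]) - 90.0, SIGMA_BOUNDS[0]]
        upper += [np.inf, float(centers[i]) + 90.0, SIGMA_BOUNDS[1]]

    try:
        popt, _ = curve_fit(
            _wrapped_gaussian_model, centers, density, p0=p0,
            bounds=(lower, upper), maxfev=500 * (len(p0) + 1), xtol=1e-12,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"Gaussian peak fit did not converge ({len(p0) // 3} components, "
            f"n={histogram.n}): {err}"
        ) from None
    rss = float(np.sum((_wrapped_gaussian_model(centers, *popt) - density) ** 2))

    n_comp = len(popt) // 3
    amp_floor = RELATIVE_PEAK_FLOOR * max(popt[3 * j] for j in range(n_comp))
    best = None
    for j in range(n_comp):
        amp, mu, sigma = popt[3 * j: 3 * j + 3]
        if amp < amp_floor:
            continue  # vanished during the joint fit: not a mode
        mu = wrap_angle(mu)
        dist = abs(mu) if abs(mu) <= 180 else 360 - abs(mu)
        cand = (dist, 0 if mu < 0 else 1, GaussianPeak(mu, float(sigma), float(amp),
                                                       rss, n_comp))
        if best is None or cand[:2] < best[:2]:
            best = cand
    return best[2]


def fit_deviations(deviations, bin_width: float = 5.0) -> GaussianPeak:
    """Convenience: histogram then fit in one call."""
    return fit_nearest_peak(histogram_deviations(deviations, bin_width))


def zscore(peak: GaussianPeak) -> ZScoreResult:
    """Z = (0 - mu)/sigma and its two-sided normal tail probability."""
    if peak.sigma <= 0:
        raise ValueError("sigma must be > 0")
    z = (0.0 - peak.mu) / peak.sigma
    probability = 2.0 * (1.0 - ndtr(abs(z)))
    return ZScoreResult(z=float(z), probability=float(probability))


def compare_to_reference(torsion_series, geometry, residue_map=None,
                         frames=None, bin_width: float = 5.0) -> dict:
    """Fit deviation peaks for all eight angles of one reference geometry.

    ``geometry`` is a DFTReferenceGeometry; ``residue_map`` maps the
    positions 'i'..'i+3' to residue ids (defaults to turn_start..+3 for
    the geometry's peptide).  Returns
    {(position, 'phi'|'psi'): (GaussianPeak, ZScoreResult)}.
    """
    from .reference_data import dft_peptides

    if residue_map is None:
        start = dft_peptides()[geometry.peptide_id]["turn_start"]
        residue_map = {pos: start + k for k, pos in enumerate(ANGLE_POSITIONS)}
    results = {}
    for k, pos in enumerate(ANGLE_POSITIONS):
        for w, which in enumerate(("phi", "psi")):
            ref = geometry.angles[2 * k + w]
            devs = deviation_series(torsion_series, residue_map[pos], which, ref,
                                    frames=frames)
            peak = fit_nearest_peak(histogram_deviations(devs, bin_width))
            results[(pos, which)] = (peak, zscore(peak))
    return results


def outlier_table(peaks: dict) -> pd.DataFrame:
    """Angles whose nearest-peak mean deviates by more than 30 deg.

    ``peaks`` maps (peptide_id, turn_type, angle_label) to a
    GaussianPeak.  Rows report |mu|, sorted by peptide then angle.
    """
    rows = [
        {"peptide": pep, "turn_type": tt, "angle": angle,
         "abs_deviation": abs(peak.mu)}
        for (pep, tt, angle), peak in peaks.items()
        if abs(peak.mu) > 30.0
    ]
    df = pd.DataFrame(rows, columns=["peptide", "turn_type", "angle",
                                     "abs_deviation"])
    return df.sort_values(["peptide", "angle", "turn_type"],
                          ignore_index=True)


def ideal_comparison_table(peaks_by_type: dict, geometry_lookup) -> pd.DataFrame:
    """|ensemble-mean angle - ideal angle| for the central residues.

    ``peaks_by_type`` maps turn_type -> {(position, which): GaussianPeak}
    for the central positions 'i+1' and 'i+2'; ``geometry_lookup`` maps
    turn_type -> DFTReferenceGeometry.  The ensemble-mean angle is
    wrap(reference + mu).  Type IV has no ideal angles and raises.
    """
    rows = []
    for turn_type, peaks in peaks_by_type.items():
        ideal = get_ideal_angles(turn_type)  # raises for IV / unknown
        geometry = geometry_lookup[turn_type]
        for k, pos in enumerate(("i+1", "i+2")):
            for w, which in enumerate(("phi", "psi")):
                key = (pos, which)
                if key not in peaks:
                    continue
                peak = peaks[key]
                reference = geometry.angles[2 * (k + 1) + w]
                mean_md = wrap_angle(reference + peak.mu)
                diff = abs(circular_difference(mean_md, ideal[2 * k + w]))
                rows.append({
                    "turn_type": turn_type, "position": pos, "angle": which,
                    "abs_difference": float(diff),
                })
    return pd.DataFrame(rows, columns=["turn_type", "position", "angle",
                                       "abs_difference"])
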