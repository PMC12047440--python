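"""Mass-photometry analysis: calibration, histograms, oligomer deconvolution,
cooperative hexamer-dissociation fits, and the RNA footprint occupancy model.

Mass photometry records the interferometric-scattering contrast of single
protein molecules landing on glass; contrast is proportional to molecular
mass. The pipeline converts contrasts to masses via a standard curve, bins
them into a fixed 100-bin / 8-kDa histogram, and deconvolves oligomeric
species (monomer, trimer, hexamer, higher-order) as Gaussian peaks whose
areas give relative species fractions.

The footprint model quantifies how many ORF1p trimers can bind an RNA of a
given length: each trimer occupies a 30-nt footprint and successive trimers
repeat with a 45-nt periodicity (a 15-nt linker between neighbours).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "MassCalibration",
    "MassHistogram",
    "OligomerFit",
    "TitrationSeries",
    "HillDissociationFit",
    "FootprintModel",
    "calibrate",
    "apply_calibration",
    "build_histogram",
    "smooth_histogram",
    "fit_oligomer_peaks",
    "fit_hill_dissociation",
    "max_trimers",
    "saturation_excess",
    "round_sigfig",
]

N_BINS = 100
BIN_WIDTH_KDA = 8.0
SPECIES = (1, 3, 6)  # monomer, trimer, hexamer; ">6" handled as a free peak
H_BOUNDS = (0.1, 10.0)


@dataclass
class MassCalibration:
    """Linear contrast-to-mass calibration: mass = slope * contrast + intercept."""

    slope: float
    intercept: float
    residuals_kda: np.ndarray
    standard_labels: list[str] = field(default_factory=list)
    slope_stderr: float | None = None
    intercept_stderr: float | None = None


@dataclass
class MassHistogram:
    """Fixed-width mass histogram (100 bins of exactly 8 kDa)."""

    bin_edges: np.ndarray  # 101 edges
    counts: np.ndarray  # 100 integer counts
    n_out_of_range: int = 0
    smoothed_counts: np.ndarray | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class OligomerFit:
    """Deconvolved oligomer species from a mass histogram.

    ``species`` labels are "1", "3", "6" and ">6"; fractions are fitted
    Gaussian areas divided by the total area and sum to one.
    """

    species: list[str]
    peak_mass: dict[str, float]
    peak_sd: dict[str, float]
    area: dict[str, float]
    fraction: dict[str, float]


@dataclass
class TitrationSeries:
    """Relative trimer fraction versus RNA concentration."""

    rna_conc: np.ndarray
    trimer_fraction: np.ndarray
    sem: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.rna_conc = np.asarray(self.rna_conc, dtype=float)
        self.trimer_fraction = np.asarray(self.trimer_fraction, dtype=float)
        if np.any(self.rna_conc < 0) or np.any(np.diff(self.rna_conc) <= 0):
            raise ValueError("concentrations must be nonnegative and strictly increasing")


@dataclass
class HillDissociationFit:
    """Hill fit of RNA-induced hexamer dissociation (trimer release).

    h > 1 indicates cooperativity: RNA binding to one trimer of a hexamer
    promotes dissociation, exposing the second trimer's binding site.
    """

    h: float
    k_half: float
    f_min: float
    f_max: float
    stderr: dict[str, float | None]
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass(frozen=True)
class FootprintModel:
    """Occupancy rule for trimers assembling along an RNA.

    footprint: nt of RNA occupied by one trimer (default 30).
    spacing: nt between successive trimer start positions (default 45,
        i.e. a 15-nt linker separates neighbouring footprints).
    """

    footprint: int = 30
    spacing: int = 45
    monomers_per_trimer: int = 3

    def __post_init__(self) -> None:
        if not (self.spacing >= self.footprint > 0):
            raise ValueError("require spacing >= footprint > 0")


def calibrate(standard_contrasts: dict[str, np.ndarray], known_masses: dict[str, float]) -> MassCalibration:
    """Fit the contrast-to-mass line through (median contrast, known mass).

    Requires at least two standards with distinct median contrasts. A crude
    multimodality check on each standard's contrast distribution emits a
    warning when more than one dominant mode is present.
    """
    labels = [lab for lab in standard_contrasts if lab in known_masses]
    if len(labels) < 2:
        raise ValueError("calibration requires at least 2 standards with known masses")
    medians, masses = [], []
    for lab in labels:
        c = np.asarray(standard_contrasts[lab], dtype=float)
        _warn_if_multimodal(c, lab)
        medians.append(np.median(c))
        masses.append(known_masses[lab])
    medians, masses = np.array(medians), np.array(masses)
    if np.ptp(medians) == 0:
        raise ValueError("degenerate calibration: identical median contrasts")
    if len(labels) >= 3:
        (slope, intercept), cov = np.polyfit(medians, masses, 1, cov=True)
        slope_se, intercept_se = (float(x) for x in np.sqrt(np.diag(cov)))
    else:
        slope, intercept = np.polyfit(medians, masses, 1)
        slope_se = intercept_se = None
    residuals = masses - (slope * medians + intercept)
    return MassCalibration(slope=float(slope), intercept=float(intercept),
                           residuals_kda=residuals, standard_labels=labels,
                           slope_stderr=slope_se, intercept_stderr=intercept_se)


def _warn_if_multimodal(contrasts: np.ndarray, label: str) -> None:
    if contrasts.size < 50:
        return
    counts, _ = np.histogram(contrasts, bins=30)
    smooth = np.convolve(counts, np.ones(5) / 5, mode="same")
    peaks, _ = find_peaks(smooth, height=0.5 * smooth.max(), distance=5)
    if peaks.size > 1:
        warnings.warn(f"standard '{label}' contrast distribution looks multimodal")


def apply_calibration(contrasts, cal: MassCalibration) -> np.ndarray:
    """Transform measured contrasts into masses (kDa) via the standard curve."""
    return cal.slope * np.asarray(contrasts, dtype=float) + cal.intercept


def build_histogram(masses, lower_edge: float = 0.0) -> MassHistogram:
    """Bin masses into 100 uniform bins of exactly 8 kDa from ``lower_edge``.

    Out-of-range events are counted and reported but excluded from the bins,
    so sum(counts) + n_out_of_range equals the input size.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.size == 0:
        raise ValueError("cannot build a histogram from zero events")
    if not np.all(np.isfinite(masses)):
        raise ValueError("masses must be finite")
    edges = lower_edge + BIN_WIDTH_KDA * np.arange(N_BINS + 1)
    in_range = (masses >= edges[0]) & (masses < edges[-1])
    counts, _ = np.histogram(masses[in_range], bins=edges)
    return MassHistogram(bin_edges=edges, counts=counts,
                         n_out_of_range=int((~in_range).sum()))


def smooth_histogram(hist: MassHistogram, window: int = 9, polyorder: int = 2) -> MassHistogram:
    """Savitzky-Golay smoothing (order 2, 9-bin span) for visualization.

    Raw counts are preserved; peak fitting operates on raw counts.
    """
    if hist.counts.size < window:
        raise ValueError(f"window {window} exceeds bin count {hist.counts.size}")
    smoothed = savgol_filter(hist.counts.astype(float), window, polyorder)
    return replace(hist, smoothed_counts=smoothed)


def _gaussian(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def fit_oligomer_peaks(hist: MassHistogram, monomer_mass: float = 40.0,
                       area_floor: float = 0.01, init_sd: float = 12.0) -> OligomerFit:
    """Deconvolve monomer/trimer/hexamer/higher-order Gaussian peaks.

    Gaussians are initialized at s x monomer_mass for s in {1, 3, 6} with
    means constrained to +/-25% of initialization (absorbing RNA-induced
    mass shifts), plus one unconstrained high-mass component for ">6".
    Fractions are fitted areas over total area; species whose fraction
    falls below ``area_floor`` are reported as zero and the remainder
    renormalized. Fitting uses the raw (unsmoothed) counts.
    """
    if monomer_mass <= 0:
        raise ValueError("monomer_mass must be positive")
    x = hist.centers
    y = hist.counts.astype(float)
    n_events = y.sum()
    labels = [str(s) for s in SPECIES] + [">6"]
    n_params = 3 * len(labels)
    if n_events < 10 * n_params:
        warnings.warn(f"only {n_events:.0f} events for {n_params} parameters; fit may be unstable")

    model = None
    params = lmfit.Parameters()
    for s in SPECIES:
        mu = s * monomer_mass
        comp = lmfit.Model(_gaussian, prefix=f"s{s}_")
        model = comp if model is None else model + comp
        params.add(f"s{s}_amp", value=max(y.max() / 10.0, 1.0), min=0.0)
        params.add(f"s{s}_mu", value=mu, min=0.75 * mu, max=1.25 * mu)
        params.add(f"s{s}_sd", value=init_sd, min=BIN_WIDTH_KDA / 2, max=8 * init_sd)
    comp = lmfit.Model(_gaussian, prefix="hi_")
    model = model + comp
    hi_init = 9 * monomer_mass
    params.add("hi_amp", value=max(y.max() / 20.0, 1.0), min=0.0)
    params.add("hi_mu", value=hi_init, min=6.5 * monomer_mass, max=float(hist.bin_edges[-1]))
    params.add("hi_sd", value=2 * init_sd, min=BIN_WIDTH_KDA / 2, max=16 * init_sd)

    result = model.fit(y, params, x=x, method="least_squares")
    if not result.success:
        raise RuntimeError(f"oligomer peak fit did not converge: {result.message}")

    prefixes = [f"s{s}_" for s in SPECIES] + ["hi_"]
    peak_mass, peak_sd, area = {}, {}, {}
    for lab, pre in zip(labels, prefixes):
        amp = result.params[pre + "amp"].value
        sd = result.params[pre + "sd"].value
        peak_mass[lab] = result.params[pre + "mu"].value
        peak_sd[lab] = sd
        # events under the Gaussian, in histogram-count units
        area[lab] = amp * sd * math.sqrt(2 * math.pi) / BIN_WIDTH_KDA
    total = sum(area.values())
    if total <= 0:
        raise RuntimeError("oligomer peak fit produced zero total area")
    fraction = {lab: a / total for lab, a in area.items()}
    kept = {lab: f for lab, f in fraction.items() if f >= area_floor}
    norm = sum(kept.values())
    fraction = {lab: (kept[lab] / norm if lab in kept else 0.0) for lab in labels}
    return OligomerFit(species=labels, peak_mass=peak_mass, peak_sd=peak_sd,
                       area=area, fraction=fraction)


def _hill_dissociation(c, f_min, f_max, k_half, h):
    c = np.asarray(c, dtype=float)
    ch = np.where(c > 0, c**h, 0.0)
    return f_min + (f_max - f_min) * ch / (k_half**h + ch)


def fit_hill_dissociation(series: TitrationSeries) -> HillDissociationFit:
    """Fit the four-parameter Hill model to a trimer-fraction titration.

    p3(c) = f_min + (f_max - f_min) * c^h / (K_half^h + c^h). Standard
    errors come from the fit covariance; h hitting its (0.1, 10) bounds
    raises a warning.
    """
    c, y = series.rna_conc, series.trimer_fraction
    if c.size < 5 or c[0] != 0:
        raise ValueError("need at least 5 concentration points including 0")
    model = lmfit.Model(_hill_dissociation, independent_vars=["c"])
    span = max(y.max() - y.min(), 1e-6)
    half = y.min() + span / 2
    k_init = float(np.interp(half, y, c)) if np.all(np.diff(y) >= 0) else float(np.median(c[c > 0]))
    params = model.make_params(
        f_min=dict(value=float(y.min()), min=-0.5, max=1.5),
        f_max=dict(value=float(y.max()), min=-0.5, max=1.5),
        k_half=dict(value=max(k_init, 1e-6), min=1e-9),
        h=dict(value=1.5, min=H_BOUNDS[0], max=H_BOUNDS[1]),
    )
    result = model.fit(y, params, c=c, method="least_squares")
    if not result.success:
        raise RuntimeError(f"Hill dissociation fit did not converge: {result.message}")
    h_val = result.params["h"].value
    if np.isclose(h_val, H_BOUNDS[0]) or np.isclose(h_val, H_BOUNDS[1]):
        warnings.warn(f"Hill coefficient at bound ({h_val:.3g})")
    return HillDissociationFit(
        h=h_val,
        k_half=result.params["k_half"].value,
        f_min=result.params["f_min"].value,
        f_max=result.params["f_max"].value,
        stderr={name: result.params[name].stderr for name in ("h", "k_half", "f_min", "f_max")},
        fitted=result.best_fit,
    )


def max_trimers(rna_length: int, model: FootprintModel = FootprintModel()) -> int:
    """Maximum number of trimers that fit on an RNA of ``rna_length`` nt.

    Zero below one footprint; thereafter one more trimer every ``spacing``
    nt: floor((L - footprint) / spacing) + 1.
    """
    if rna_length < 0:
        raise ValueError("RNA length must be nonnegative")
    if rna_length < model.footprint:
        return 0
    return (int(rna_length) - model.footprint) // model.spacing + 1


def saturation_excess(rna_length: int, model: FootprintModel = FootprintModel()) -> tuple[int, float]:
    """Monomer:RNA molar ratio that saturates all direct trimer sites.

    Returns the exact value (monomers_per_trimer x max_trimers) together
    with the same number rounded to two significant figures.
    """
    exact = model.monomers_per_trimer * max_trimers(rna_length, model)
    return exact, round_sigfig(exact, 2)


def round_sigfig(value: float, sig: int) -> float:
    if value == 0:
        return 0.0
    return round(value, -int(math.floor(math.log10(abs(value)))) + (sig - 1))
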