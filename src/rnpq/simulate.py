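"""Synthetic-data generators with known ground truth for every pipeline stage.

Every generator draws from a single seeded NumPy generator (sub-streams are
spawned deterministically per cell or DNA so enlarging a dataset does not
perturb earlier entries) and returns the dataset together with a
:class:`GroundTruth` record; downstream recovery tests read truth only from
that record, never from the data.

Noise models are the simplest consistent with the measurements: Gaussian
mass noise for landing events, Gaussian anisotropy noise, Poisson event
counts with exponential right-censored dwell times on curtains, and
Gaussian point-spread profiles over Gaussian background in images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .binding import BindingCurve, CompetitionSystem, hill, solve_competition
from .curtains import GenomeTrack

__all__ = [
    "SimConfig",
    "GroundTruth",
    "MassEventSet",
    "ImageStack",
    "STANDARD_MASSES_KDA",
    "gen_mass_events",
    "gen_anisotropy_curve",
    "gen_curtain_events",
    "gen_spot_images",
    "synthetic_lambda_genome",
]

# Nominal masses (kDa) of the calibration standards; configuration values,
# not instrument constants (BSA monomer, ovalbumin, aldolase tetramer as in
# gel-filtration HMW calibration kits).
STANDARD_MASSES_KDA = {"BSA": 66.5, "ovalbumin": 44.0, "aldolase": 158.0}

STAGES = ("massphot", "binding", "curtains", "spots")


@dataclass
class SimConfig:
    """Seed + stage + stage-specific parameters; fixed seed => identical data."""

    seed: int
    stage: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        for key, val in self.parameters.items():
            if key.endswith(("_conc", "_mean", "_rate")) and np.isscalar(val) and val is not None:
                if float(val) <= 0:
                    raise ValueError(f"parameter {key} must be strictly positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"seed": self.seed, "stage": self.stage,
                            "parameters": _plain(self.parameters)}, fh)


@dataclass
class GroundTruth:
    """True parameter values serialized alongside every generated dataset."""

    stage: str
    true_values: dict

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"stage": self.stage, "true_values": _plain(self.true_values)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(stage=d["stage"], true_values=d["true_values"])


def _plain(obj):
    """Recursively convert numpy scalars/arrays for clean YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class MassEventSet:
    """Single-landing contrast events from one acquisition, plus the
    contrast events of the calibration standards recorded alongside."""

    contrasts: np.ndarray
    standard_contrasts: dict[str, np.ndarray]
    calibration_truth: tuple[float, float]  # (slope, intercept), kDa per contrast


def gen_mass_events(species: list[tuple[float, float]], n_events: int,
                    mass_noise_sd: float, calibration: tuple[float, float] = (1000.0, 0.0),
                    seed: int = 0, n_standard_events: int = 2000,
                    standard_masses: dict[str, float] | None = None
                    ) -> tuple[MassEventSet, GroundTruth]:
    """Draw landing-event contrasts from a mixture of oligomer masses.

    ``species`` is a list of (mass kDa, fraction); masses are drawn from the
    corresponding normal components (sd = ``mass_noise_sd``) and converted
    to contrasts via c = (m - intercept) / slope. A matching standards set
    is generated for the calibration species so the full contrast-to-mass
    round trip can be exercised.
    """
    masses = np.array([m for m, _ in species], dtype=float)
    fractions = np.array([f for _, f in species], dtype=float)
    if np.any(masses <= 0):
        raise ValueError("species masses must be positive")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"species fractions must sum to 1 (got {fractions.sum()})")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    slope, intercept = calibration
    if slope == 0:
        raise ValueError("calibration slope must be nonzero")
    if mass_noise_sd < 0:
        raise ValueError("mass noise sd must be nonnegative")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(masses), size=n_events, p=fractions)
    drawn = rng.normal(masses[comp], mass_noise_sd)
    contrasts = (drawn - intercept) / slope
    standard_masses = standard_masses or STANDARD_MASSES_KDA
    standards = {
        lab: (rng.normal(m, mass_noise_sd, size=n_standard_events) - intercept) / slope
        for lab, m in standard_masses.items()
    }
    truth = GroundTruth(stage="massphot", true_values={
        "species_mass_kda": masses.tolist(),
        "species_fraction": fractions.tolist(),
        "mass_noise_sd_kda": mass_noise_sd,
        "calibration_slope": slope,
        "calibration_intercept": intercept,
        "standard_masses_kda": dict(standard_masses),
    })
    return MassEventSet(contrasts=contrasts, standard_contrasts=standards,
                        calibration_truth=(slope, intercept)), truth


def gen_anisotropy_curve(kd: float, h: float, r_free: float, r_bound: float,
                         protein_concs, noise_sd: float, seed: int = 0,
                         competitor: tuple[float, float] | None = None,
                         labeled_total: float = 1.0,
                         ) -> tuple[BindingCurve, GroundTruth]:
    """Simulate an anisotropy titration with Hill or competition structure.

    Without a competitor the expected signal is
    r(P) = r_free + (r_bound - r_free) * P^h / (kd^h + P^h); with a
    competitor (kd_c, conc_c) the bound fraction comes from the exact
    coupled-equilibrium solver (single shared site; h is ignored there as
    competition is modeled per binding unit). Gaussian noise of
    ``noise_sd`` anisotropy units is added to every point including the
    protein-free blank.
    """
    protein_concs = np.asarray(protein_concs, dtype=float)
    if protein_concs.size == 0:
        raise ValueError("empty concentration grid")
    if kd <= 0 or h <= 0:
        raise ValueError("kd and h must be positive")
    if r_bound == r_free:
        raise ValueError("r_bound must differ from r_free")
    if np.any(protein_concs < 0) or np.any(np.diff(protein_concs) <= 0):
        raise ValueError("concentrations must be nonnegative and strictly increasing")
    if competitor is None or competitor[1] == 0:
        theta = hill(protein_concs, kd, h)
    else:
        kd_c, conc_c = competitor
        sys = CompetitionSystem(kd_labeled=kd, kd_competitor=kd_c,
                                labeled_total=labeled_total, competitor_total=conc_c,
                                protein_total=protein_concs)
        theta = solve_competition(sys)
    rng = np.random.default_rng(seed)
    expected = r_free + (r_bound - r_free) * theta
    raw = expected + rng.normal(0.0, noise_sd, size=expected.size)
    blank = r_free + rng.normal(0.0, noise_sd)
    truth = GroundTruth(stage="binding", true_values={
        "kd_nM": kd, "h": h, "r_free": r_free, "r_bound": r_bound,
        "noise_sd": noise_sd,
        "competitor_kd_nM": None if competitor is None else competitor[0],
        "competitor_conc_nM": None if competitor is None else competitor[1],
        "labeled_total_nM": labeled_total,
    })
    return BindingCurve(protein_conc=protein_concs, raw_anisotropy=raw,
                        blank_anisotropy=blank), truth


def _position_weights(genome: GenomeTrack, bias: str, weight: float) -> np.ndarray:
    n = genome.length_bp
    w = np.ones(n)
    if bias == "uniform":
        pass
    elif bias == "at_weighted":
        is_at = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
        w[(is_at == ord("A")) | (is_at == ord("T"))] = weight
    elif bias == "motif_weighted":
        for start, _ in genome.motif_sites:
            w[start - 1:start - 1 + len(genome.motif)] = weight
    else:
        raise ValueError(f"unknown position bias scheme: {bias}")
    return w / w.sum()


def gen_curtain_events(genome: GenomeTrack, n_dna: int, events_per_dna_mean: float,
                       dwell_mean_s: float, movie_length_s: float,
                       position_bias: str = "uniform", bias_weight: float = 1.0,
                       dual_label_prob: float = 0.0, amplitude: tuple[float, float] = (100.0, 10.0),
                       n_experiments: int = 1, seed: int = 0,
                       start_at_zero: bool = False,
                       ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a curtain event table with sequence-biased positions.

    Per-DNA event counts are Poisson(``events_per_dna_mean``); positions are
    drawn from the chosen bias over the genome (``at_weighted`` multiplies
    the density at A/T bases by ``bias_weight``; ``motif_weighted`` does the
    same at motif-site bases); dwell times are exponential with mean
    ``dwell_mean_s``, right-censored at movie end with the censor flag set.
    With ``dual_label_prob`` > 0 each condensate independently carries both
    colors with that probability (two linked rows, one per channel).
    """
    if genome.length_bp <= 0:
        raise ValueError("genome length must be positive")
    if movie_length_s <= 0 or dwell_mean_s <= 0:
        raise ValueError("movie length and dwell mean must be positive")
    weights = _position_weights(genome, position_bias, bias_weight)
    root = np.random.default_rng(seed)
    # one sub-stream per (experiment, dna): adding DNAs never perturbs earlier ones
    streams = root.spawn(n_experiments * n_dna)
    rows = []
    event_id = 0
    for exp in range(n_experiments):
        for dna in range(n_dna):
            rng = streams[exp * n_dna + dna]
            n_ev = rng.poisson(events_per_dna_mean)
            for _ in range(n_ev):
                pos_bp = rng.choice(genome.length_bp, p=weights)
                t_start = 0.0 if start_at_zero else rng.uniform(0.0, movie_length_s)
                dwell = rng.exponential(dwell_mean_s)
                t_end = t_start + dwell
                censored = t_end >= movie_length_s
                if censored:
                    t_end = movie_length_s
                amp = max(rng.normal(*amplitude), 0.0)
                dual = rng.uniform() < dual_label_prob
                base = dict(experiment_id=exp, fov_id=0, dna_id=dna,
                            position_kbp=pos_bp / 1000.0, t_start_s=t_start,
                            t_end_s=t_end, censored=censored, amplitude=amp)
                rows.append(dict(base, event_id=event_id, channel="green",
                                 partner_event_id=event_id + 1 if dual else -1))
                if dual:
                    rows.append(dict(base, event_id=event_id + 1, channel="red",
                                     partner_event_id=event_id))
                    event_id += 1
                event_id += 1
    cols = ["experiment_id", "fov_id", "dna_id", "event_id", "position_kbp",
            "t_start_s", "t_end_s", "censored", "channel", "amplitude", "partner_event_id"]
    table = pd.DataFrame(rows, columns=cols)
    truth = GroundTruth(stage="curtains", true_values={
        "events_per_dna_mean": events_per_dna_mean, "dwell_mean_s": dwell_mean_s,
        "movie_length_s": movie_length_s, "position_bias": position_bias,
        "bias_weight": bias_weight, "dual_label_prob": dual_label_prob,
        "amplitude_mean": amplitude[0], "amplitude_sd": amplitude[1],
        "n_dna": n_dna, "n_experiments": n_experiments,
    })
    return table, truth


@dataclass
class ImageStack:
    """Multi-channel 3D image (z, y, x) with named channels."""

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float] = (0.3, 0.1, 0.1)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        if any(np.any(c < 0) for c in self.channels.values()):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


def _add_gaussian_spot(img: np.ndarray, center, sigma: float, amplitude: float) -> None:
    cz, cy, cx = center
    r = max(int(np.ceil(4 * sigma)), 2)
    zs = slice(max(cz - r, 0), min(cz + r + 1, img.shape[0]))
    ys = slice(max(cy - r, 0), min(cy + r + 1, img.shape[1]))
    xs = slice(max(cx - r, 0), min(cx + r + 1, img.shape[2]))
    zz, yy, xx = np.meshgrid(np.arange(zs.start, zs.stop), np.arange(ys.start, ys.stop),
                             np.arange(xs.start, xs.stop), indexing="ij")
    img[zs, ys, xs] += amplitude * np.exp(
        -((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


def _ellipse_mask(shape_yx, center, semi_axes) -> np.ndarray:
    yy, xx = np.ogrid[: shape_yx[0], : shape_yx[1]]
    cy, cx = center
    ay, ax = semi_axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def gen_spot_images(n_cells: int, image_shape: tuple[int, int, int] = (16, 128, 128),
                    n_spots_per_cell: int = 10, psf_sigma: float = 1.5,
                    colocalized_fraction: float = 0.0,
                    spot_intensity: dict[str, float] | None = None,
                    background_sd: float = 10.0, background_mean: float = 100.0,
                    nuclear_fraction: float = 0.0, poisson_spots: bool = False,
                    seed: int = 0,
                    ) -> tuple[ImageStack, np.ndarray, pd.DataFrame, GroundTruth]:
    """Render 3D multi-channel cell images with diffraction-limited puncta.

    Cells are disjoint ellipses laid out on a grid; each cell's nucleus (a
    concentric half-size ellipse) is rendered in the dna channel. RNA spots
    are placed uniformly inside the cell footprint (outside the nucleus
    unless assigned nuclear by ``nuclear_fraction``) and rendered as
    isotropic 3D Gaussians in the rna channel; a fraction
    ``colocalized_fraction`` of them also receives a protein-channel
    Gaussian at the same voxel. With ``poisson_spots`` the per-cell spot
    count is Poisson with mean ``n_spots_per_cell`` instead of fixed.
    Returns the stack, the 2D labeled ROI mask, the ground-truth spot
    table and the GroundTruth record.
    """
    if psf_sigma < 0.5:
        raise ValueError("psf_sigma must be at least 0.5 voxel")
    if not 0.0 <= colocalized_fraction <= 1.0:
        raise ValueError("colocalized_fraction must be a probability")
    nz, ny, nx = image_shape
    spot_intensity = spot_intensity or {"rna": 400.0, "protein": 400.0, "dna": 300.0}
    grid = int(np.ceil(np.sqrt(n_cells)))
    cell_h, cell_w = ny // grid, nx // grid
    semi = (0.42 * cell_h, 0.42 * cell_w)
    if min(semi) < 3:
        raise ValueError("image too small for the requested cell count")
    mask = np.zeros((ny, nx), dtype=np.uint16)
    channels = {name: np.zeros(image_shape) for name in ("dna", "protein", "rna")}
    root = np.random.default_rng(seed)
    streams = root.spawn(n_cells)
    rows = []
    for cell in range(n_cells):
        gy, gx = divmod(cell, grid)
        cy, cx = gy * cell_h + cell_h // 2, gx * cell_w + cell_w // 2
        cell_mask = _ellipse_mask((ny, nx), (cy, cx), semi)
        if (mask[cell_mask] != 0).any():
            raise ValueError("cell ROIs overlap")  # grid layout makes this impossible
        mask[cell_mask] = cell + 1
        nuc_semi = (semi[0] / 2, semi[1] / 2)
        nuc_mask = _ellipse_mask((ny, nx), (cy, cx), nuc_semi)
        # nucleus rendered as a bright slab through the central z planes
        z_lo, z_hi = nz // 4, 3 * nz // 4
        channels["dna"][z_lo:z_hi, nuc_mask] += spot_intensity["dna"]
        rng = streams[cell]
        cyto_pix = np.argwhere(cell_mask & ~nuc_mask)
        nuc_pix = np.argwhere(nuc_mask)
        n_spots = rng.poisson(n_spots_per_cell) if poisson_spots else n_spots_per_cell
        for _ in range(n_spots):
            nuclear = rng.uniform() < nuclear_fraction
            pool = nuc_pix if nuclear else cyto_pix
            y, x = pool[rng.integers(len(pool))]
            z = int(rng.integers(z_lo, z_hi)) if nuclear else int(rng.integers(2, nz - 2))
            coloc = bool(rng.uniform() < colocalized_fraction)
            _add_gaussian_spot(channels["rna"], (z, y, x), psf_sigma, spot_intensity["rna"])
            if coloc:
                _add_gaussian_spot(channels["protein"], (z, y, x), psf_sigma,
                                   spot_intensity["protein"])
            rows.append(dict(x=int(x), y=int(y), z=z, roi=cell + 1,
                             compartment="nuclear" if nuclear else "cytoplasmic",
                             colocalized=coloc))
    noise_rng = root.spawn(1)[0]
    for name in channels:
        channels[name] = np.clip(
            channels[name] + noise_rng.normal(background_mean, background_sd, size=image_shape),
            0.0, None)
    stack = ImageStack(channels=channels)
    truth_table = pd.DataFrame(rows, columns=["x", "y", "z", "roi", "compartment", "colocalized"])
    truth = GroundTruth(stage="spots", true_values={
        "n_cells": n_cells, "n_spots_per_cell": n_spots_per_cell,
        "colocalized_fraction": colocalized_fraction, "psf_sigma": psf_sigma,
        "spot_intensity": dict(spot_intensity), "background_sd": background_sd,
        "background_mean": background_mean, "nuclear_fraction": nuclear_fraction,
    })
    return stack, mask, truth_table, truth


def synthetic_lambda_genome(length: int = 48502, n_forward: int = 7, n_reverse: int = 5,
                            motif: str = "TTTTTAA", gc_fraction: float = 0.498,
                            seed: int = 20250925) -> str:
    """SYNTHETIC stand-in for a lambda-scale curtain substrate.

    A deterministic random sequence of the lambda-phage genome's length and
    GC content in which every spontaneous occurrence of ``motif`` (on
    either strand) is scrubbed and exactly ``n_forward`` + ``n_reverse``
    sites are planted at evenly spaced positions (reverse sites planted as
    the motif's reverse complement). This is NOT the NC_001416 sequence; it
    provides a genome with exactly known motif ground truth for testing the
    scanner and position-bias analyses at full substrate scale.
    """
    from .curtains import find_motif_sites, reverse_complement

    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2
    p_at = (1 - gc_fraction) / 2
    bases = np.array(list("ACGT"))
    s = "".join(rng.choice(bases, size=length, p=[p_at, p_gc, p_gc, p_at]))
    rc = reverse_complement(motif)
    positions = (np.linspace(0.04, 0.96, n_forward + n_reverse) * (length - len(motif))).astype(int)
    planted_seqs = [motif] * n_forward + [rc] * n_reverse
    rng.shuffle(planted_seqs)
    for _ in range(100):
        chars = list(s)
        for planted, pos in zip(planted_seqs, positions):
            chars[pos:pos + len(motif)] = planted
        s = "".join(chars)
        # scrub spontaneous occurrences (including any created at plant edges)
        keep = {int(p) + 1 for p in positions}
        stray = [st for st, _ in find_motif_sites(s, motif, "both") if st not in keep]
        if not stray:
            break
        chars = list(s)
        protected = {i for p in positions for i in range(p, p + len(motif))}
        for st in stray:
            cand = [i for i in range(st - 1, st - 1 + len(motif)) if i not in protected]
            flip = cand[len(cand) // 2]
            chars[flip] = "G" if chars[flip] in "AT" else "C"
        s = "".join(chars)
    return s
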