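"""DNA-curtains event analysis.

DNA curtains stretch arrays of lambda-phage DNA between chromium barriers in
a flow cell; binding of labeled ribonucleoprotein condensates is imaged by
TIRF microscopy and reduced upstream to an event table (one row per binding
event: DNA molecule, position along the DNA in kbp, start/stop time,
channel, amplitude). This module computes the per-DNA binding statistics,
two-color colocalization, binding-position histograms against motif and
A/T-content genome tracks, dwell-time survival with bootstrap errors, and
kymograms.

Event tables are pandas DataFrames with unit-bearing column names:
``experiment_id, fov_id, dna_id, event_id, position_kbp, t_start_s,
t_end_s, censored, channel, amplitude, partner_event_id``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeTrack",
    "PositionHistogram",
    "SurvivalCurve",
    "events_per_dna",
    "normalize_per_rna",
    "weighted_average",
    "colocalization_fraction",
    "position_histogram",
    "find_motif_sites",
    "reverse_complement",
    "at_content_track",
    "position_enrichment_test",
    "kaplan_meier",
    "survival_at",
    "mean_event_amplitude",
    "build_kymogram",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_SEQ = re.compile(r"^[ACGT]+$")

# lambda substrate: 24 bins of exactly 2 kbp from the barrier anchor
POSITION_BINS = 24
POSITION_BIN_KBP = 2.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeTrack:
    """A DNA sequence with motif-site and windowed A/T-content annotations."""

    sequence: str
    motif: str = "TTTTTAA"
    at_window_bp: int = 1000
    at_step_bp: int = 500
    motif_sites: list[tuple[int, str]] = field(init=False)
    at_content: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not _VALID_SEQ.match(self.sequence):
            raise ValueError("sequence must be nonempty uppercase ACGT")
        self.motif_sites = find_motif_sites(self.sequence, self.motif, strand_policy="both")
        self.at_content = at_content_track(self.sequence, self.at_window_bp, self.at_step_bp)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def at_fraction_at(self, positions_bp) -> np.ndarray:
        """A/T fraction of the window whose center is nearest each position."""
        centers = self.at_content["center_bp"].to_numpy()
        values = self.at_content["at_fraction"].to_numpy()
        idx = np.clip(np.searchsorted(centers, np.asarray(positions_bp)), 0, centers.size - 1)
        left = np.clip(idx - 1, 0, centers.size - 1)
        pick_left = np.abs(centers[left] - positions_bp) <= np.abs(centers[idx] - positions_bp)
        return values[np.where(pick_left, left, idx)]


@dataclass
class PositionHistogram:
    """Binding positions in 24 fixed bins of 2 kbp from the barrier."""

    bin_edges_kbp: np.ndarray
    counts: np.ndarray
    n_out_of_range: int = 0
    normalization: str = "counts"


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate with a percentile bootstrap band."""

    time_s: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_events: int
    n_censored: int


def events_per_dna(table: pd.DataFrame, dna_counts: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Binding events per DNA strand, averaged across experiments.

    ``dna_counts`` has columns experiment_id, fov_id, n_dna. Per experiment,
    total events are divided by total DNA strands; the mean and SEM across
    experiments are returned alongside the per-experiment values.
    """
    if (dna_counts["n_dna"] <= 0).any():
        raise ValueError("n_dna must be positive for every fov")
    fovs_seen = set(map(tuple, table[["experiment_id", "fov_id"]].drop_duplicates().to_numpy()))
    fovs_known = set(map(tuple, dna_counts[["experiment_id", "fov_id"]].to_numpy()))
    missing = fovs_seen - fovs_known
    if missing:
        raise ValueError(f"missing dna_counts for fovs: {sorted(missing)}")
    ev = table.groupby("experiment_id").size()
    dna = dna_counts.groupby("experiment_id")["n_dna"].sum()
    per_exp = (ev.reindex(dna.index, fill_value=0) / dna).astype(float)
    mean = float(per_exp.mean())
    sem = float(per_exp.std(ddof=1) / np.sqrt(len(per_exp))) if len(per_exp) > 1 else 0.0
    return per_exp, mean, sem


def normalize_per_rna(events_per_dna_value: float, rna_conc_nm: float) -> float:
    """Events per DNA per nM of RNA (the labeled species)."""
    if rna_conc_nm <= 0:
        raise ValueError("RNA concentration must be positive")
    return events_per_dna_value / rna_conc_nm


def weighted_average(values, weights) -> float:
    """Weighted mean; weights are the number of DNA strands per experiment."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    return float(np.sum(values * weights) / weights.sum())


def colocalization_fraction(table: pd.DataFrame, max_distance_kbp: float = 1.0,
                            max_time_offset_s: float = 1.0) -> tuple[float, float]:
    """Fraction of condensates carrying both colors, with binomial SEM.

    Cross-channel events on the same DNA are greedily paired nearest-first
    when both the position offset and the start-time offset fall within the
    thresholds; a paired pair counts as one condensate. Symmetric under
    channel swap.
    """
    channels = table["channel"].unique()
    if len(channels) < 2:
        raise ValueError("colocalization requires at least two channels")
    ch_a, ch_b = sorted(channels)[:2]
    n_pairs = 0
    n_a = n_b = 0
    for _, grp in table.groupby(["experiment_id", "fov_id", "dna_id"]):
        a = grp[grp["channel"] == ch_a]
        b = grp[grp["channel"] == ch_b]
        n_a += len(a)
        n_b += len(b)
        if a.empty or b.empty:
            continue
        # all admissible cross-channel pairs, nearest (in position) first
        cand = []
        for ia, ra in a.iterrows():
            for ib, rb in b.iterrows():
                d = abs(ra["position_kbp"] - rb["position_kbp"])
                dt = abs(ra["t_start_s"] - rb["t_start_s"])
                if d <= max_distance_kbp and dt <= max_time_offset_s:
                    cand.append((d, ia, ib))
        used_a: set = set()
        used_b: set = set()
        for d, ia, ib in sorted(cand, key=lambda t: t[0]):
            if ia not in used_a and ib not in used_b:
                used_a.add(ia)
                used_b.add(ib)
                n_pairs += 1
    n_condensates = n_a + n_b - n_pairs
    if n_condensates == 0:
        raise ValueError("no events in table")
    frac = n_pairs / n_condensates
    sem = float(np.sqrt(frac * (1 - frac) / n_condensates))
    return frac, sem


def position_histogram(table: pd.DataFrame | np.ndarray) -> PositionHistogram:
    """Histogram of binding positions: 24 half-open [lo, hi) bins of 2 kbp.

    Out-of-range positions are counted, reported and excluded; in-range
    counts are conserved.
    """
    positions = table["position_kbp"].to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table, float)
    edges = POSITION_BIN_KBP * np.arange(POSITION_BINS + 1)
    in_range = (positions >= edges[0]) & (positions < edges[-1])
    counts, _ = np.histogram(positions[in_range], bins=edges)
    return PositionHistogram(bin_edges_kbp=edges, counts=counts,
                             n_out_of_range=int((~in_range).sum()))


def find_motif_sites(sequence: str, motif: str, strand_policy: str = "both") -> list[tuple[int, str]]:
    """All exact (possibly overlapping) motif occurrences, 1-based starts.

    Under ``both``, occurrences of the reverse complement on the forward
    sequence are also reported, annotated with strand "-" (the biological
    target is strand-defined but curtains cannot distinguish strands).
    """
    sequence = sequence.upper()
    if not motif or not _VALID_SEQ.match(motif):
        raise ValueError("motif must be nonempty uppercase ACGT")
    if not _VALID_SEQ.match(sequence):
        raise ValueError("sequence must be nonempty uppercase ACGT")
    if strand_policy not in ("forward", "both"):
        raise ValueError(f"unknown strand policy: {strand_policy}")
    sites = [(m.start() + 1, "+") for m in re.finditer(f"(?={motif})", sequence)]
    if strand_policy == "both":
        rc = reverse_complement(motif)
        rev = [(m.start() + 1, "-") for m in re.finditer(f"(?={rc})", sequence)]
        if rc == motif:  # palindromic motif: forward hits already cover both strands
            rev = []
        sites = sorted(sites + rev)
    return sites


def at_content_track(sequence: str, window_bp: int, step_bp: int | None = None) -> pd.DataFrame:
    """Sliding-window A/T fraction with window-center coordinates (1-based)."""
    if window_bp <= 0:
        raise ValueError("window must be positive")
    if window_bp > len(sequence):
        raise ValueError("window exceeds sequence length")
    step_bp = step_bp or window_bp
    is_at = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_at = ((is_at == ord("A")) | (is_at == ord("T"))).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(is_at)])
    starts = np.arange(0, len(sequence) - window_bp + 1, step_bp)
    frac = (csum[starts + window_bp] - csum[starts]) / window_bp
    centers = starts + (window_bp + 1) / 2.0  # 1-based window center
    return pd.DataFrame({"start_bp": starts + 1, "center_bp": centers, "at_fraction": frac})


def position_enrichment_test(positions_kbp, track: GenomeTrack, n_permutations: int = 1000,
                             seed: int = 0) -> tuple[float, float]:
    """Permutation test for A/T enrichment of binding positions.

    The score is the mean windowed A/T fraction at the observed positions;
    the null resamples the same number of positions uniformly along the
    genome. p = (1 + #null >= observed) / (1 + n_permutations).
    """
    positions_kbp = np.asarray(positions_kbp, dtype=float)
    if positions_kbp.size == 0:
        raise ValueError("no positions supplied")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    pos_bp = positions_kbp * 1000.0
    score = float(np.mean(track.at_fraction_at(pos_bp)))
    rng = np.random.default_rng(seed)
    null_pos = rng.uniform(0, track.length_bp, size=(n_permutations, positions_kbp.size))
    null_scores = track.at_fraction_at(null_pos.ravel()).reshape(n_permutations, -1).mean(axis=1)
    p = (1 + int(np.sum(null_scores >= score))) / (1 + n_permutations)
    return score, p


def _product_limit(times: np.ndarray, observed: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Kaplan-Meier S(t) evaluated on ``grid`` (right-continuous steps)."""
    order = np.argsort(times, kind="stable")
    times, observed = times[order], observed[order]
    event_times = np.unique(times[observed])
    s_vals = []
    s = 1.0
    for t in event_times:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & observed)
        s *= 1.0 - d / at_risk
        s_vals.append(s)
    s_vals = np.array(s_vals)
    idx = np.searchsorted(event_times, grid, side="right") - 1
    out = np.where(idx >= 0, s_vals[np.clip(idx, 0, None)], 1.0) if s_vals.size else np.ones_like(grid)
    return out


def kaplan_meier(lifetimes, censored, n_bootstrap: int = 1000, seed: int = 0) -> SurvivalCurve:
    """Product-limit survival estimate with a percentile bootstrap 95% band.

    ``censored`` flags right-censored lifetimes (the event persisted at
    movie end). The band resamples events with replacement; it always
    contains the point estimate.
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    observed = ~censored
    if not observed.any():
        raise ValueError("all lifetimes censored: no events to estimate from")
    if n_bootstrap < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    grid = np.concatenate([[0.0], np.unique(lifetimes)])
    s = _product_limit(lifetimes, observed, grid)
    rng = np.random.default_rng(seed)
    n = lifetimes.size
    boot = np.empty((n_bootstrap, grid.size))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if not observed[idx].any():  # degenerate resample: no events
            boot[b] = 1.0
            continue
        boot[b] = _product_limit(lifetimes[idx], observed[idx], grid)
    lo = np.minimum(np.quantile(boot, 0.025, axis=0), s)
    hi = np.maximum(np.quantile(boot, 0.975, axis=0), s)
    return SurvivalCurve(time_s=grid, survival=s, ci_lower=lo, ci_upper=hi,
                         n_events=int(observed.sum()), n_censored=int(censored.sum()))


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """S(t) of the right-continuous step function."""
    idx = np.searchsorted(curve.time_s, t, side="right") - 1
    return float(curve.survival[max(idx, 0)])


def mean_event_amplitude(table: pd.DataFrame, condition_col: str | None = None):
    """Time-averaged fluorescence amplitude per event, plus condition summary.

    If the table holds one row per frame (repeated event_id), frames are
    averaged per event first; a single-frame event's amplitude is that
    frame's value.
    """
    per_event = table.groupby("event_id")["amplitude"].mean()
    if condition_col is None:
        summary = pd.DataFrame({"mean": [per_event.mean()], "sd": [per_event.std(ddof=1)],
                                "n_events": [len(per_event)]})
    else:
        cond = table.groupby("event_id")[condition_col].first()
        df = pd.DataFrame({"amplitude": per_event, condition_col: cond})
        summary = df.groupby(condition_col)["amplitude"].agg(["mean", "std", "count"])
    return per_event, summary


def build_kymogram(traces: pd.DataFrame, n_frames: int, genome_length_kbp: float = 48.5,
                   n_position_bins: int = 512, background: float = 0.0) -> tuple[np.ndarray, list[int]]:
    """Position x time intensity matrix from per-DNA event traces.

    ``traces`` has columns frame, position_kbp, intensity with a uniform
    frame interval. Frames with no sample are filled with ``background``
    and their indices reported.
    """
    kymo = np.full((n_position_bins, n_frames), background, dtype=float)
    pos_idx = np.clip((traces["position_kbp"] / genome_length_kbp * n_position_bins).astype(int),
                      0, n_position_bins - 1)
    frames = traces["frame"].astype(int)
    if (frames < 0).any() or (frames >= n_frames).any():
        raise ValueError("trace frame index outside movie")
    np.add.at(kymo, (pos_idx.to_numpy(), frames.to_numpy()), traces["intensity"].to_numpy())
    missing = sorted(set(range(n_frames)) - set(frames))
    return kymo, missing
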