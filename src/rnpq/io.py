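"""Shared readers/writers, configuration and the pipeline runner.

Tables travel as TSV with unit-bearing column names (position_kbp,
t_start_s, ...); sequences as standard FASTA; configuration, simulation
parameters and ground truth as YAML side-cars. Sequence positions are
1-based inclusive in reports and 0-based half-open internally.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO

__all__ = [
    "RunManifest",
    "read_fasta",
    "read_event_table",
    "write_event_table",
    "write_image_stack",
    "read_image_stack",
    "write_labeled_mask",
    "read_labeled_mask",
    "EVENT_TABLE_SCHEMA",
    "run_pipeline",
]

EVENT_TABLE_SCHEMA = {
    "experiment_id": "int64",
    "fov_id": "int64",
    "dna_id": "int64",
    "event_id": "int64",
    "position_kbp": "float64",
    "t_start_s": "float64",
    "t_end_s": "float64",
    "censored": "bool",
    "channel": "object",
    "amplitude": "float64",
    "partner_event_id": "int64",
}


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, digests, seed, outputs."""

    seed: int
    config_hash: str
    started: float
    stages: dict[str, dict] = field(default_factory=dict)
    completed: bool = False

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_fasta(path, rna_as_dna: bool = False) -> list[tuple[str, str]]:
    """Read FASTA records (multi-line allowed) as (id, uppercase sequence).

    With ``rna_as_dna`` every U is converted to T so RNA sequences can feed
    the DNA-track analyses.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rna_as_dna:
            seq = seq.replace("U", "T")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_event_table(path, schema: dict[str, str] = EVENT_TABLE_SCHEMA) -> pd.DataFrame:
    """Read and validate a TSV event table against a declared schema.

    Missing required columns raise; extra columns are preserved with a
    warning; rows violating basic invariants (negative dwell, end before
    start) are rejected and counted in ``attrs['n_rejected']``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"extra columns preserved: {extra}")
    for col, dtype in schema.items():
        df[col] = df[col].astype(dtype)
    ok = (df["t_end_s"] >= df["t_start_s"]) & (df["t_start_s"] >= 0) & (df["position_kbp"] >= 0)
    rejected = int((~ok).sum())
    out = df[ok].reset_index(drop=True)
    out.attrs["n_rejected"] = rejected
    return out


def write_event_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_image_stack(stack, path) -> None:
    """Write a multi-channel 3D stack as multi-page TIFF, channel-major then z.

    Channel names and order are stored in the TIFF description so the
    paired reader restores the stack field-for-field.
    """
    names = sorted(stack.channels)
    pages = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(str(path), pages, metadata={"axes": "CZYX"},
                     description=json.dumps({"channels": names,
                                             "voxel_size_um": list(stack.voxel_size_um)}))


def read_image_stack(path):
    """Read a stack written by :func:`write_image_stack`."""
    from .simulate import ImageStack

    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    channels = {name: data[i].astype(float) for i, name in enumerate(meta["channels"])}
    return ImageStack(channels=channels, voxel_size_um=tuple(meta["voxel_size_um"]))


def write_labeled_mask(mask: np.ndarray, path) -> None:
    """Write a 2D labeled ROI mask as 16-bit TIFF."""
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit a 16-bit mask")
    tifffile.imwrite(str(path), mask.astype(np.uint16))


def read_labeled_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.uint16)


def _stage_simulate(params: dict, seed: int, out: Path) -> dict:
    from . import simulate

    stage = params["stage"]
    out.mkdir(parents=True, exist_ok=True)
    if stage == "massphot":
        events, truth = simulate.gen_mass_events(
            species=[tuple(s) for s in params.get("species", [(120.0, 0.3), (240.0, 0.7)])],
            n_events=params.get("n_events", 20000),
            mass_noise_sd=params.get("mass_noise_sd", 12.0), seed=seed)
        pd.DataFrame({"contrast": events.contrasts}).to_csv(out / "events.tsv", sep="\t", index=False)
        for lab, c in events.standard_contrasts.items():
            pd.DataFrame({"contrast": c}).to_csv(out / f"standard_{lab}.tsv", sep="\t", index=False)
    elif stage == "curtains":
        from .curtains import GenomeTrack

        genome = GenomeTrack(simulate.synthetic_lambda_genome())
        table, truth = simulate.gen_curtain_events(
            genome, n_dna=params.get("n_dna", 50),
            events_per_dna_mean=params.get("events_per_dna_mean", 3.0),
            dwell_mean_s=params.get("dwell_mean_s", 750.0),
            movie_length_s=params.get("movie_length_s", 600.0), seed=seed)
        write_event_table(table, out / "events.tsv")
    else:
        raise ValueError(f"pipeline simulate stage not supported: {stage}")
    truth.to_yaml(out / "ground_truth.yaml")
    return {"out": str(out)}


def _stage_massphot(params: dict, seed: int, out: Path) -> dict:
    from . import massphot
    from .simulate import STANDARD_MASSES_KDA

    src = Path(params["events_dir"])
    contrasts = pd.read_csv(src / "events.tsv", sep="\t")["contrast"].to_numpy()
    standards = {lab: pd.read_csv(src / f"standard_{lab}.tsv", sep="\t")["contrast"].to_numpy()
                 for lab in STANDARD_MASSES_KDA}
    cal = massphot.calibrate(standards, STANDARD_MASSES_KDA)
    masses = massphot.apply_calibration(contrasts, cal)
    hist = massphot.smooth_histogram(massphot.build_histogram(masses))
    fit = massphot.fit_oligomer_peaks(hist)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"bin_center_kda": hist.centers, "count": hist.counts,
                  "smoothed": hist.smoothed_counts}).to_csv(out / "histogram.csv", index=False)
    with open(out / "oligomer_fit.json", "w") as fh:
        json.dump({"species": fit.species, "peak_mass_kda": fit.peak_mass,
                   "peak_sd_kda": fit.peak_sd, "fraction": fit.fraction,
                   "calibration": {"slope": cal.slope, "intercept": cal.intercept}}, fh, indent=2)
    return {"out": str(out)}


_STAGE_RUNNERS = {"simulate": _stage_simulate, "massphot": _stage_massphot}

_CONFIG_KEYS = {"seed", "out_dir", "stages"}


def run_pipeline(config: dict | str | Path) -> RunManifest:
    """Execute configured stages in order and write a run manifest.

    ``config`` is a dict or YAML path with keys seed, out_dir and stages
    (list of {name, params}). Invalid keys fail before any stage runs; a
    stage failure leaves the manifest recording partial completion.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"invalid config key(s): {sorted(unknown)}")
    for st in config["stages"]:
        if st["name"] not in _STAGE_RUNNERS:
            raise ValueError(f"unknown stage: {st['name']}")
    seed = int(config.get("seed", 0))
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(seed=seed, config_hash=cfg_hash, started=time.time())
    try:
        for st in config["stages"]:
            info = _STAGE_RUNNERS[st["name"]](st.get("params", {}), seed, out_dir / st["name"])
            outputs = sorted(Path(info["out"]).iterdir())
            info["digests"] = {p.name: _digest(p) for p in outputs if p.is_file()}
            manifest.stages[st["name"]] = info
        manifest.completed = True
    finally:
        manifest.to_json(out_dir / "manifest.json")
    return manifest
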