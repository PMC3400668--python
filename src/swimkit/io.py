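"""Readers and writers for the tabular and sequence formats the pipeline uses.

Plain-text formats only: CSV/TSV for traces, trajectories and tables (with
``# key=value`` metadata headers where a file needs scalar context), TPS for
landmark configurations, FASTA (via Biopython) for alignments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidParameterError
from .faststart import FastStartTrajectory
from .morpho import LandmarkConfig
from .popgen import AlignedSequences
from .respirometry import O2Trace


# -- metadata-header CSVs ----------------------------------------------------

def _write_csv_with_meta(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def write_o2_trace(path, trace: O2Trace) -> None:
    df = pd.DataFrame({"time_min": trace.times, "o2_mg_per_l": trace.o2})
    meta = {
        "resp_volume_l": trace.resp_volume,
        "fish_volume_l": trace.fish_volume,
        "fish_mass_kg": trace.fish_mass,
    }
    if trace.speed is not None:
        meta["speed_cm_s"] = trace.speed
    _write_csv_with_meta(path, df, meta)


def read_o2_trace(path) -> O2Trace:
    df, meta = _read_csv_with_meta(path)
    return O2Trace(
        times=df["time_min"].to_numpy(),
        o2=df["o2_mg_per_l"].to_numpy(),
        resp_volume=float(meta["resp_volume_l"]),
        fish_volume=float(meta["fish_volume_l"]),
        fish_mass=float(meta["fish_mass_kg"]),
        speed=float(meta["speed_cm_s"]) if "speed_cm_s" in meta else None,
    )


def write_trajectory(path, traj: FastStartTrajectory) -> None:
    df = pd.DataFrame({"frame": traj.frames, "x_mm": traj.x, "y_mm": traj.y})
    _write_csv_with_meta(path, df, {"fps": traj.fps, "stim_frame": traj.stim_frame})


def read_trajectory(path) -> FastStartTrajectory:
    df, meta = _read_csv_with_meta(path)
    return FastStartTrajectory(
        frames=df["frame"].to_numpy(),
        x=df["x_mm"].to_numpy(),
        y=df["y_mm"].to_numpy(),
        fps=float(meta["fps"]),
        stim_frame=int(meta["stim_frame"]),
    )


def write_mo2_series(path, points) -> None:
    pd.DataFrame(points, columns=["speed_cm_s", "mo2"]).to_csv(path, index=False)


def read_mo2_series(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return list(zip(df["speed_cm_s"].astype(float), df["mo2"].astype(float)))


# -- TPS landmark files ------------------------------------------------------

def write_tps(path, configs: list[LandmarkConfig], scale: float | None = None) -> None:
    """Write configurations in TPS format (LM= count, x y pairs, ID= label)."""
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.k}\n")
            for x, y in cfg.coords:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={cfg.specimen_id}\n")
            if scale is not None:
                fh.write(f"SCALE={scale:.10g}\n")


def read_tps(path) -> list[LandmarkConfig]:
    """Read a TPS landmark file (LM=, coordinate pairs, ID=, optional SCALE=)."""
    configs: list[LandmarkConfig] = []
    coords: list[list[float]] = []
    expected = 0
    ident: str | None = None
    scale: float | None = None

    def flush(index: int) -> None:
        nonlocal coords, ident, scale
        if expected == 0:
            return
        if len(coords) != expected:
            raise InvalidParameterError(
                f"TPS record {index}: expected {expected} landmarks, read {len(coords)}"
            )
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        configs.append(
            LandmarkConfig(specimen_id=ident or f"record{index}", coords=arr)
        )
        coords, ident, scale = [], None, None

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                if expected:
                    flush(len(configs))
                expected = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                ident = line.split("=", 1)[1]
            elif upper.startswith("SCALE="):
                scale = float(line.split("=", 1)[1])
            elif upper.startswith(("IMAGE=", "CURVES=", "POINTS=")):
                continue
            else:
                parts = line.split()
                coords.append([float(parts[0]), float(parts[1])])
    flush(len(configs))
    return configs


# -- FASTA + group labels ----------------------------------------------------

def write_fasta(path, aln: AlignedSequences) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, path, "fasta")


def write_groups(path, aln: AlignedSequences) -> None:
    pd.DataFrame({"id": aln.ids, "group": aln.groups}).to_csv(path, sep="\t", index=False)


def read_fasta_with_groups(fasta_path, groups_path) -> AlignedSequences:
    records = list(SeqIO.parse(fasta_path, "fasta"))
    groups_df = pd.read_csv(groups_path, sep="\t").set_index("id")
    ids = [r.id for r in records]
    missing = [i for i in ids if i not in groups_df.index]
    if missing:
        raise InvalidParameterError(f"sequences without group labels: {missing}")
    return AlignedSequences(
        ids=ids,
        sequences=[str(r.seq) for r in records],
        groups=[str(groups_df.loc[i, "group"]) for i in ids],
    )


# -- distance matrices and tables --------------------------------------------

def write_distance_matrix(path, ids, d: np.ndarray) -> None:
    pd.DataFrame(d, index=ids, columns=ids).to_csv(path, sep="\t")


def write_phylip_matrix(path, ids, d: np.ndarray) -> None:
    """Square PHYLIP-style distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i, sid in enumerate(ids):
            row = " ".join(f"{v:.6f}" for v in d[i])
            fh.write(f"{sid:<10s} {row}\n")


def site_table_frame(sites) -> pd.DataFrame:
    from dataclasses import asdict

    return pd.DataFrame([asdict(s) for s in sites])


def write_site_table(path, sites) -> None:
    site_table_frame(sites).to_csv(path, sep="\t", index=False)
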