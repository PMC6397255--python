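"""Format round-trips: FASTA strands, reaction-system JSON, length/trace CSV,
population JSON and YAML run configs.

All CSV headers carry units (length_nm, time_s, intensity_au).  Every writer
has a reader such that read(write(x)) == x on canonical field order.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chain_growth import ChainState, PopulationState
from .dispersity import LengthSample
from .photobleach import Trace
from .tile_model import (
    DomainAnnotation,
    ReactionSystem,
    StickyPair,
    StrandSpec,
    TileSpec,
)

__all__ = [
    "write_fasta", "read_fasta",
    "write_system_json", "read_system_json",
    "write_lengths_csv", "read_lengths_csv",
    "write_traces_csv", "read_traces_csv",
    "write_population_json", "read_population_json",
    "read_config_yaml", "write_config_yaml",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------- FASTA

def _labels_to_desc(labels: dict[str, str]) -> str:
    return " ".join(f"{end}={lab}" for end, lab in sorted(labels.items()))


def _desc_to_labels(desc: str) -> dict[str, str]:
    labels = {}
    for tok in desc.split():
        if "=" in tok:
            end, lab = tok.split("=", 1)
            if end in ("5p", "3p"):
                labels[end] = lab
    return labels


def write_fasta(strands: list[StrandSpec], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.name, description=_labels_to_desc(s.labels))
        for s in strands
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> list[StrandSpec]:
    """Strands from FASTA; lowercase sequences are normalized to uppercase
    with a warning."""
    strands = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"strand {rec.id}: lowercase normalized to uppercase")
            seq = seq.upper()
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        strands.append(StrandSpec(rec.id, seq, labels=_desc_to_labels(desc)))
    return strands


# --------------------------------------------------------- system JSON

def _strand_dict(s: StrandSpec) -> dict:
    return {"name": s.name, "sequence": s.sequence, "labels": dict(s.labels)}


def _tile_dict(t: TileSpec) -> dict:
    return {
        "tile_id": t.tile_id,
        "strands": [_strand_dict(s) for s in t.strands],
        "domains": [dataclasses.asdict(d) for d in t.domains],
        "sticky_pairs": [dataclasses.asdict(p) for p in t.sticky_pairs],
        "crossover_separation_nt": t.crossover_separation_nt,
        "tile_length_bp": t.tile_length_bp,
    }


def write_system_json(system: ReactionSystem, path: PathLike) -> None:
    doc = {
        "tiles": [_tile_dict(t) for t in system.tiles.values()],
        "initiator": _strand_dict(system.initiator) if system.initiator else None,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_system_json(path: PathLike) -> ReactionSystem:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed system JSON at line {e.lineno}: {e.msg}")
    tiles = {}
    for td in doc.get("tiles", []):
        tile = TileSpec(
            tile_id=td["tile_id"],
            strands=[StrandSpec(**sd) for sd in td["strands"]],
            domains=[DomainAnnotation(**dd) for dd in td["domains"]],
            sticky_pairs=[StickyPair(**pd) for pd in td.get("sticky_pairs", [])],
            crossover_separation_nt=td.get("crossover_separation_nt", 26),
            tile_length_bp=td.get("tile_length_bp", 47),
        )
        tiles[tile.tile_id] = tile
    init = doc.get("initiator")
    initiator = StrandSpec(**init) if init else None
    return ReactionSystem(tiles=tiles, initiator=initiator)


# --------------------------------------------------------- lengths CSV

def write_lengths_csv(sample: LengthSample, path: PathLike) -> None:
    df = pd.DataFrame(
        {"length_nm": sample.values, "multiplicity": sample.multiplicities}
    )
    df.to_csv(path, index=False)


def read_lengths_csv(path: PathLike, allow_zero: bool = False) -> LengthSample:
    df = pd.read_csv(path)
    col = None
    for cand in ("length_nm", "value", "length", "length_tiles"):
        if cand in df.columns:
            col = cand
            break
    if col is None:
        raise ValueError(f"{path}: no length column (expected length_nm or value)")
    mult = df["multiplicity"] if "multiplicity" in df.columns else None
    return LengthSample(df[col].to_numpy(),
                        None if mult is None else mult.to_numpy(),
                        allow_zero=allow_zero)


# ----------------------------------------------------------- traces CSV

def write_traces_csv(traces: list[Trace], path: PathLike) -> None:
    frames = []
    for i, t in enumerate(traces):
        frames.append(
            pd.DataFrame(
                {"trace_id": i, "time_s": t.times, "intensity_au": t.intensities}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: PathLike) -> list[Trace]:
    df = pd.read_csv(path)
    for col in ("time_s", "intensity_au"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "trace_id" not in df.columns:
        df["trace_id"] = 0
    traces = []
    for _, g in df.groupby("trace_id", sort=True):
        traces.append(Trace(g["time_s"].to_numpy(), g["intensity_au"].to_numpy()))
    return traces


# ------------------------------------------------------ population JSON

def write_population_json(pop: PopulationState, path: PathLike) -> None:
    doc = {
        "free_A": pop.free_A,
        "free_B": pop.free_B,
        "free_I": pop.free_I,
        "mode": pop.mode,
        "chains": [
            {"n_tiles": c.n_tiles, "active_terminus": c.active_terminus}
            for c in pop.chains
        ],
        "rng_state": pop.rng_state,
        "meta": pop.meta,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=int) + "\n")


def read_population_json(path: PathLike) -> PopulationState:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed population JSON at line {e.lineno}: {e.msg}")
    return PopulationState(
        free_A=doc["free_A"],
        free_B=doc["free_B"],
        free_I=doc["free_I"],
        chains=[ChainState(**cd) for cd in doc["chains"]],
        rng_state=doc.get("rng_state"),
        mode=doc.get("mode", "ideal"),
        meta=doc.get("meta", {}),
    )


# ------------------------------------------------------------ YAML config

def read_config_yaml(path: PathLike) -> dict:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ValueError(f"{path}: malformed YAML: {e}")
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return doc


def write_config_yaml(config: dict, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
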