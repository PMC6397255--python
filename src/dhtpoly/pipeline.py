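"""Reproducible multi-stage pipeline: fixtures -> simulate -> stats / bleach /
mech, with a JSON manifest of inputs, seeds, versions and output checksums.

One global seed is supplied in the config; per-stage substreams are derived
deterministically from it, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as dio
from .chain_growth import SimParams, simulate_living
from .dispersity import LengthSample, dispersity_summary, fit_poisson, label_counts
from .mechanics import RodParams, build_rod, compute_rmsf, dsdna_design, \
    filament_design, relative_compliance
from .photobleach import step_histogram
from .synthetic import NoiseModel, gen_afm_lengths, gen_trace_batch, generate_tile_set
from .tile_model import HelixGeometry, validate_system

__all__ = ["RunConfig", "run_pipeline", "DependencyError"]

log = logging.getLogger("dhtpoly")

STAGE_ORDER = ["fixtures", "simulate", "stats", "bleach", "mech"]


class DependencyError(RuntimeError):
    """A stage was requested without its upstream artifact."""


@dataclass
class RunConfig:
    stages: list[str]
    seed: int = 0
    out_dir: str = "dht_run"
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        stages = doc.get("stages")
        if not stages:
            raise ValueError("config must list at least one stage")
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        return cls(
            stages=[s for s in STAGE_ORDER if s in stages],
            seed=int(doc.get("seed", 0)),
            out_dir=str(doc.get("out_dir", "dht_run")),
            log_level=str(doc.get("log_level", "INFO")),
            params={s: dict(doc.get(s, {})) for s in STAGE_ORDER},
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(dio.read_config_yaml(path))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([global_seed, STAGE_ORDER.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order and return the
    manifest (also written to <out_dir>/manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)

    from . import __version__

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": config.stages,
        "stage_seeds": {},
        "outputs": {},
    }
    artifacts: dict[str, Path] = {}

    try:
        for stage in config.stages:
            seed = _stage_seed(config.seed, stage)
            manifest["stage_seeds"][stage] = seed
            p = config.params.get(stage, {})
            log.info("stage %s (seed %d)", stage, seed)

            if stage == "fixtures":
                system = generate_tile_set(seed=seed,
                                           stem_len=int(p.get("stem_len", 8)),
                                           loop_len=int(p.get("loop_len", 6)))
                sys_path = out / "system.json"
                fa_path = out / "strands.fa"
                dio.write_system_json(system, sys_path)
                strands = [s for t in system.tiles.values() for s in t.strands]
                if system.initiator:
                    strands.append(system.initiator)
                dio.write_fasta(strands, fa_path)
                violations = validate_system(system)
                (out / "violations.json").write_text(
                    json.dumps([v.__dict__ for v in violations], indent=2) + "\n"
                )
                artifacts["system"] = sys_path
                artifacts["fasta"] = fa_path

            elif stage == "simulate":
                params = SimParams(
                    ratio_MI=float(p.get("ratio", 10)),
                    n_initiators=int(p.get("n_initiators", 10_000)),
                    mode=p.get("mode", "ideal"),
                    seed=seed,
                )
                pop = simulate_living(params)
                pop_path = out / "population.json"
                dio.write_population_json(pop, pop_path)
                noise = NoiseModel(
                    length_noise_sd=float(p.get("noise_sd", 8.0)),
                    min_detectable_nm=float(p.get("floor_nm", 10.0)),
                )
                sample, dropped = gen_afm_lengths(
                    pop, noise, tile_length_nm=float(p.get("tile_nm", 16.0)),
                    seed=seed + 1,
                )
                len_path = out / "lengths.csv"
                dio.write_lengths_csv(sample, len_path)
                artifacts["population"] = pop_path
                artifacts["lengths"] = len_path
                manifest["outputs"]["simulate.n_dropped"] = dropped

            elif stage == "stats":
                if "lengths" not in artifacts:
                    raise DependencyError(
                        "stats requires the simulate stage (no lengths.csv)"
                    )
                sample = dio.read_lengths_csv(artifacts["lengths"])
                summ = dispersity_summary(sample)
                doc = {
                    "Ln": summ.Ln, "Lw": summ.Lw, "sigma": summ.sigma,
                    "PDI": summ.PDI, "N": summ.N,
                }
                if p.get("poisson", True) and "population" in artifacts:
                    pop = dio.read_population_json(artifacts["population"])
                    hist = label_counts(pop, 1.0, seed=seed,
                                        truncated=bool(p.get("truncated", True)))
                    fit = fit_poisson(hist)
                    doc["poisson"] = {
                        "lambda_hat": fit.lambda_hat,
                        "truncated": fit.truncated,
                        "loglik": fit.log_likelihood,
                    }
                path = out / "summary.json"
                path.write_text(json.dumps(doc, indent=2) + "\n")
                artifacts["summary"] = path

            elif stage == "bleach":
                if "population" not in artifacts:
                    raise DependencyError(
                        "bleach requires the simulate stage (no population.json)"
                    )
                pop = dio.read_population_json(artifacts["population"])
                traces = gen_trace_batch(
                    pop,
                    noise_sd=1.0 / float(p.get("snr", 5.0)),
                    seed=seed,
                    max_traces=int(p.get("n_traces", 100)),
                )
                tr_path = out / "traces.csv"
                dio.write_traces_csv(traces, tr_path)
                hist = step_histogram(traces)
                (out / "steps.json").write_text(
                    json.dumps({str(k): v for k, v in sorted(hist.counts.items())},
                               indent=2) + "\n"
                )
                artifacts["traces"] = tr_path

            elif stage == "mech":
                params = RodParams()
                geom = HelixGeometry()
                ref = build_rod(dsdna_design(24), geom, params)
                rod = build_rod(
                    filament_design(int(p.get("n_ab", 10))), geom, params
                )
                prof = compute_rmsf(rod, params)
                import pandas as pd

                df = pd.DataFrame({
                    "node_index": np.arange(prof.rmsf_nm.size),
                    "arc_nm": prof.positions_nm,
                    "rmsf_nm": prof.rmsf_nm,
                })
                rmsf_path = out / "rmsf.csv"
                df.to_csv(rmsf_path, index=False)
                (out / "mech_summary.json").write_text(json.dumps({
                    "min_rmsf_nm": prof.min_rmsf,
                    "max_rmsf_nm": prof.max_rmsf,
                    "relative_compliance_vs_dsDNA24":
                        relative_compliance(ref, rod,
                                            exponent=int(p.get("exponent", 3))),
                }, indent=2) + "\n")
                artifacts["rmsf"] = rmsf_path
    finally:
        log.removeHandler(fh)
        fh.close()

    for name, path in artifacts.items():
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
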