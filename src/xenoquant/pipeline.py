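"""End-to-end orchestration of the benchmark on synthetic data.

``run_benchmark`` executes generate -> digest -> simulate -> per-policy
quantify -> DEP analysis -> (PDX) evaluation, writing every stage output as
TSV/FASTA into the run directory together with a JSON manifest holding the
config, seeds, per-stage timings, row counts and sha256 checksums.  Reruns
with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .dep_analysis import calibrate_thresholds, dep_count_matrix, fit_power_law
from .digestion import IndexParams, build_peptide_index, write_index_tsv
from .quantification import psm_ratio, quantify, write_quant_tsv
from .species_assignment import Policy
from .synthetic_proteome import (
    MixtureDesign,
    ParameterError,
    generate_paired_proteomes,
    make_benchmark_designs,
    read_design_tsv,
    simulate_mixture,
    write_design_tsv,
    write_fasta,
    write_psm_tsv,
)
from .xeno_eval import (
    benchmark_pdx_models,
    intra_pdx_deps,
    sweep_min_ratio,
    write_sweep_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one benchmark run; serialized verbatim into the manifest."""

    design: str = "cell_line"  # "cell_line" | "pdx" | path to a design TSV
    policies: tuple[str, ...] = ("full_peptide", "unique_peptide", "human_only")
    n_proteins: int = 500
    mean_length: int = 400
    mutation_rate: float = 0.012
    ortholog_fraction: float = 0.8
    missed_cleavages: int = 2
    min_peptide_length: int = 7
    max_peptide_length: int = 45
    collapse_IL: bool = True
    noise_cv: float = 0.3
    psm_rate: float = 0.2
    fdr: float = 0.01
    min_ratio_grid: tuple[float, ...] = tuple(
        float(x) for x in np.round(np.arange(1.2, 3.01, 0.2), 10)
    )
    seed: int = 0
    output_dir: str = "xenoquant_run"

    def validate(self) -> None:
        for p in self.policies:
            Policy(p)  # raises on unknown policy
        if not 0 < self.fdr < 1:
            raise ParameterError("fdr must be in (0, 1)")
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("policies", "min_ratio_grid"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["policies"] = list(d["policies"])
        d["min_ratio_grid"] = list(d["min_ratio_grid"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _resolve_design(config: RunConfig) -> MixtureDesign:
    cell_line, pdx = make_benchmark_designs()
    if config.design == "cell_line":
        return cell_line
    if config.design == "pdx":
        return pdx
    return read_design_tsv(config.design)


def run_benchmark(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    from . import __version__
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "checksums": {},
        "row_counts": {},
    }
    written: list[Path] = []

    def _stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc_type is not None:
                    logger.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
                    manifest["stages"][name] = {"seconds": round(dt, 3), "status": "failed"}
                    _write_manifest()
                    return False
                manifest["stages"][name] = {"seconds": round(dt, 3), "status": "ok"}
                logger.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Timer()

    def _write_manifest() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    rng_seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)

    with _stage("generate"):
        pair = generate_paired_proteomes(
            config.n_proteins,
            config.mean_length,
            config.mutation_rate,
            seed=int(rng_seeds[0]),
            ortholog_fraction=config.ortholog_fraction,
        )
        write_fasta(pair.human, out / "human.fasta")
        write_fasta(pair.mouse, out / "mouse.fasta")
        written += [out / "human.fasta", out / "mouse.fasta"]
        design = _resolve_design(config)
        write_design_tsv(design, out / "design.tsv")
        written.append(out / "design.tsv")
        manifest["row_counts"]["design.tsv"] = len(design.channels)

    with _stage("digest"):
        index = build_peptide_index(
            pair,
            IndexParams(
                missed_cleavages=config.missed_cleavages,
                min_length=config.min_peptide_length,
                max_length=config.max_peptide_length,
                collapse_IL=config.collapse_IL,
            ),
        )
        write_index_tsv(index, out / "peptide_index.tsv")
        written.append(out / "peptide_index.tsv")
        manifest["row_counts"]["peptide_index.tsv"] = len(index.entries)
        manifest["index_class_counts"] = index.class_counts()
        manifest["common_peptide_fraction"] = round(index.common_fraction, 6)

    with _stage("simulate"):
        experiment = simulate_mixture(
            pair, index, design,
            noise_cv=config.noise_cv, psm_rate=config.psm_rate,
            seed=int(rng_seeds[1]),
        )
        write_psm_tsv(experiment, out / "psm_table.tsv")
        written.append(out / "psm_table.tsv")
        manifest["row_counts"]["psm_table.tsv"] = len(experiment.psm_table)

    matrices = {}
    for policy in config.policies:
        with _stage(f"quantify[{policy}]"):
            m = quantify(experiment, index, policy)
            matrices[policy] = m
            dpath, mpath = out / f"quant_{policy}.tsv", out / f"quant_{policy}_meta.tsv"
            write_quant_tsv(m, dpath, mpath)
            written += [dpath, mpath]
            manifest["row_counts"][dpath.name] = len(m.data)
            ratios = psm_ratio(m)
            ratios.to_csv(out / f"psm_ratio_{policy}.tsv", sep="\t", float_format="%.10g")
            written.append(out / f"psm_ratio_{policy}.tsv")

    thresholds_by_policy = {}
    with _stage("dep"):
        for policy, m in matrices.items():
            th = calibrate_thresholds(m, design, config.fdr)
            thresholds_by_policy[policy] = th
            counts = dep_count_matrix(m, design, th)
            counts.to_csv(out / f"dep_counts_{policy}.tsv", sep="\t")
            written.append(out / f"dep_counts_{policy}.tsv")
            manifest.setdefault("dep_thresholds", {})[policy] = {
                "low": th.low, "high": th.high, "degenerate": th.degenerate,
            }
            if config.design == "cell_line":
                # DEP growth vs mouse % relative to the pure-human sample
                ref = design.samples[0]
                pts = [
                    (100.0 - float(s), float(counts.loc[ref, s]))
                    for s in design.samples
                    if s != ref
                ]
                try:
                    fitted = fit_power_law(pts)
                    manifest.setdefault("power_fit", {})[policy] = {
                        "a": fitted.a, "b": fitted.b, "r_squared": fitted.r_squared,
                    }
                except ParameterError as exc:
                    logger.warning("power fit skipped for %s: %s", policy, exc)

    if config.design == "pdx":
        with _stage("eval"):
            models = benchmark_pdx_models()
            for policy, m in matrices.items():
                frame, r, p = intra_pdx_deps(m, design, models, thresholds_by_policy[policy])
                frame.to_csv(out / f"intra_pdx_{policy}.tsv", sep="\t", index=False)
                written.append(out / f"intra_pdx_{policy}.tsv")
                sweep = sweep_min_ratio(m, design, models, np.array(config.min_ratio_grid))
                write_sweep_tsv(sweep, out / f"sweep_{policy}.tsv")
                written.append(out / f"sweep_{policy}.tsv")
                manifest.setdefault("intra_pdx_correlation", {})[policy] = {
                    "pearson_r": r, "p_value": p,
                }

    for path in written:
        manifest["checksums"][path.name] = _sha256(path)
    _write_manifest()
    return out
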