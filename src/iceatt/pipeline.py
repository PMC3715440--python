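"""Pipeline runner: executes declared stages and writes a run manifest.

A run configuration names an output directory, a seed, and an ordered list
of stages. Each stage writes its outputs under the output directory and
contributes a summary to the manifest; the manifest (inputs, parameters,
seed, package version, per-stage summaries, output checksums) is sufficient
to re-run deterministic stages bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from .attsite import AttSiteCore, scan_genome, tally_sites
from .io_utils import (
    file_checksum,
    read_catalog,
    read_fasta,
    write_bed6,
    write_catalog,
    write_fasta,
    write_manifest,
)
from .popdyn import (
    CompetitionParams,
    generations_to_ratio,
    ratio,
    round_sig,
    simulate_competition,
)
from .synth import DEFAULT_REFERENCE_CORE, make_genome

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a pipeline run."""

    outdir: Path
    stages: Sequence[Mapping[str, Any]]
    seed: int = 0
    reference_core: str = DEFAULT_REFERENCE_CORE.sequence

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        return cls(
            outdir=Path(d["outdir"]),
            stages=list(d.get("stages", [])),
            seed=int(d.get("seed", 0)),
            reference_core=str(d.get("reference_core", DEFAULT_REFERENCE_CORE.sequence)),
        )


def _stage_synth_genome(cfg: RunConfig, params: Mapping[str, Any], state: dict) -> dict:
    specs = [
        (int(mm), bool(div), str(strand))
        for mm, div, strand in params.get("planted", [(0, False, "+")])
    ]
    truth = make_genome(
        int(params.get("length", 20_000)),
        specs,
        AttSiteCore(cfg.reference_core),
        gc_fraction=float(params.get("gc_fraction", 0.435)),
        seed=cfg.seed,
    )
    fasta = cfg.outdir / "genome.fasta"
    write_fasta(truth.contigs, fasta)
    state["genome"] = truth.contigs
    state["truth"] = truth
    return {"n_planted": len(truth.sites), "genome_fasta": str(fasta)}


def _stage_scan(cfg: RunConfig, params: Mapping[str, Any], state: dict) -> dict:
    genome = state.get("genome")
    if genome is None:
        path = params.get("genome")
        if path is None:
            raise PipelineError("scan: no genome from a prior stage and no 'genome' path")
        genome = read_fasta(path)
    hits = scan_genome(
        genome,
        AttSiteCore(cfg.reference_core),
        int(params.get("max_mismatch", 4)),
    )
    bed = cfg.outdir / "scan_hits.bed"
    write_bed6(hits, bed)
    state["hits"] = hits
    return {"n_hits": len(hits), "bed": str(bed)}


def _stage_tally(cfg: RunConfig, params: Mapping[str, Any], state: dict) -> dict:
    path = params.get("catalog")
    if path is not None:
        records = read_catalog(path)
    elif "hits" in state:
        # one synthetic "insertion" per scan hit, keyed by position
        from .attsite import InsertionRecord

        records = [
            InsertionRecord(
                locus=f"{h.contig}:{h.start}",
                orientation="co-directional" if h.strand == "+" else "head-on",
                occurrences=1,
                core=h.core,
                mismatches=h.mismatches,
            )
            for h in state["hits"]
        ]
    else:
        raise PipelineError("tally: no catalog path and no scan hits in state")
    summary = tally_sites(records)
    out = cfg.outdir / "tally.tsv"
    write_catalog(records, out)
    state["tally"] = summary
    return {
        "n_insertions": summary.n_insertions,
        "n_sites": summary.n_sites,
        "modal_site": summary.modal_site.locus,
        "modal_percent": summary.modal_site.percent,
        "catalog_tsv": str(out),
    }


def _stage_compete(cfg: RunConfig, params: Mapping[str, Any], state: dict) -> dict:
    R = float(params["R"])
    D = float(params["D"])
    G = generations_to_ratio(R, D)
    return {
        "R": R,
        "D": D,
        "generations": G,
        "generations_2sig": round_sig(G, 2),
        "check_ratio": ratio(G, D),
    }


def _stage_simulate(cfg: RunConfig, params: Mapping[str, Any], state: dict) -> dict:
    p = CompetitionParams(P0=float(params.get("P0", 5e5)), D=float(params["D"]))
    result = simulate_competition(
        p,
        generations=int(params["generations"]),
        n_replicates=int(params.get("replicates", 50)),
        population_cap=int(params.get("cap", 1_000_000)),
        seed=cfg.seed,
    )
    return {
        "final_ratio_mean": result.final_ratio_mean,
        "final_ratio_se": result.final_ratio_se,
        "replicates": result.counts.shape[0],
    }


_STAGES = {
    "synth_genome": _stage_synth_genome,
    "scan": _stage_scan,
    "tally": _stage_tally,
    "compete": _stage_compete,
    "simulate": _stage_simulate,
}


def run_pipeline(config: RunConfig | Mapping[str, Any]) -> dict:
    """Execute the configured stages in order and write ``manifest.json``.

    Returns the manifest dict. Stage failures raise :class:`PipelineError`
    naming the stage.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    config.outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    manifest: dict = {
        "package": "iceatt",
        "version": __version__,
        "seed": config.seed,
        "reference_core": config.reference_core,
        "stages": [],
    }
    for spec in config.stages:
        name = spec.get("stage")
        if name not in _STAGES:
            raise PipelineError(f"unknown stage {name!r}")
        params = {k: v for k, v in spec.items() if k != "stage"}
        try:
            summary = _STAGES[name](config, params, state)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"stage": name, **summary})
    # checksums for every file a stage declared
    checksums = {}
    for st in manifest["stages"]:
        for key, val in st.items():
            if isinstance(val, str) and Path(val).is_file():
                checksums[val] = file_checksum(val)
    manifest["checksums"] = checksums
    write_manifest(config.outdir / "manifest.json", manifest)
    return manifest
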