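"""Workflow orchestration, file formats and configuration.

Formats
-------
profiles      TSV, long format: gene, stage_hours, profile_id, segment_index
              (1..100), intensity
morphology    JSON: {stage_hours, outer_loop, inner_loop, oral_anchor}
reference     JSON (see ReferenceData)
ensemble      JSON (see Ensemble)
network       edge-list TSV + GraphML
dendrogram    Newick
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering, estimation, network_inference, sensitivity, synthetic_data
from . import gene_circuit as gc
from .quantification import StandardizedProfile, N_STANDARD_POINTS

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Profile tables
# ---------------------------------------------------------------------------

def profiles_to_table(profiles: Sequence[StandardizedProfile],
                      profile_ids: Sequence[str] | None = None) -> pd.DataFrame:
    if profile_ids is None:
        counter: dict[str, int] = {}
        profile_ids = []
        for p in profiles:
            counter[p.gene] = counter.get(p.gene, 0) + 1
            profile_ids.append(f"{p.gene}:{counter[p.gene]}")
    rows = []
    for p, pid in zip(profiles, profile_ids):
        for k, v in enumerate(p.values, start=1):
            rows.append((p.gene, p.stage_hours, pid, k, v))
    return pd.DataFrame(rows, columns=["gene", "stage_hours", "profile_id",
                                       "segment_index", "intensity"])


def write_profiles(profiles, path: str | Path,
                   profile_ids: Sequence[str] | None = None) -> None:
    profiles_to_table(profiles, profile_ids).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> tuple[list[StandardizedProfile], list[str]]:
    """Read a profile TSV back into StandardizedProfile objects + their ids."""
    df = pd.read_csv(path, sep="\t")
    profiles, ids = [], []
    for pid, sub in df.groupby("profile_id", sort=False):
        sub = sub.sort_values("segment_index")
        values = sub["intensity"].to_numpy()
        profiles.append(StandardizedProfile(str(sub["gene"].iloc[0]),
                                            float(sub["stage_hours"].iloc[0]),
                                            values))
        ids.append(str(pid))
    return profiles, ids


# ---------------------------------------------------------------------------
# Reference assembly
# ---------------------------------------------------------------------------

def build_reference(profiles: Sequence[StandardizedProfile],
                    profile_ids: Sequence[str],
                    selection: Mapping) -> gc.ReferenceData:
    """Assemble fitting reference data from a profile table and a selection.

    ``selection`` mirrors the fitting-input table layout::

        {"times": [0, 25, 50],
         "genes": {"foxA": {"0": "zeros", "25": "foxA:1", "50": "foxA:2"}, ...},
         "maternal": {"gene": "Bcat", "profile": "Bcat:1"}}

    The literal ``"zeros"`` means no observed expression; profiles at time 0
    initialize the simulation; the single maternal profile is held constant.
    """
    by_id = {pid: p for pid, p in zip(profile_ids, profiles)}
    times = [float(t) for t in selection["times"]]
    if times[0] != 0 or any(np.diff(times) <= 0):
        raise PipelineError("selection times must start at 0 and increase")
    genes = selection["genes"]
    maternal = selection.get("maternal")
    if not isinstance(maternal, Mapping) or "gene" not in maternal:
        raise PipelineError("selection must name exactly one maternal gene")
    mat_pid = maternal["profile"]
    if mat_pid not in by_id:
        raise PipelineError(f"missing maternal profile id {mat_pid!r}")
    mat_profile = by_id[mat_pid].values

    gene_names = tuple(genes)
    n = len(gene_names)
    A = N_STANDARD_POINTS

    def resolve(gene: str, t: float) -> np.ndarray:
        cell = None
        for key, value in genes[gene].items():
            if float(key) == t:
                cell = value
                break
        if cell is None:
            raise PipelineError(f"no profile listed for ({gene}, {t} h)")
        if str(cell).lower() == "zeros":
            return np.zeros(A)
        if cell not in by_id:
            raise PipelineError(f"missing profile id {cell!r} for ({gene}, {t} h)")
        return by_id[cell].values

    initial = np.vstack([resolve(g, times[0]) for g in gene_names])
    targets = np.stack([
        np.vstack([resolve(g, t) for g in gene_names]) for t in times[1:]
    ])
    return gc.ReferenceData(gene_names, str(maternal["gene"]), mat_profile,
                            initial, tuple(times[1:]), targets)


# ---------------------------------------------------------------------------
# Pipeline configuration and driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One self-contained run of the synthetic end-to-end workflow."""

    out_dir: str = "nemagrn_out"
    seed: int = 0
    profile_noise_sd: float = 0.05
    cut_height: float = clustering.DEFAULT_CUT_HEIGHT
    run_clustering: bool = True
    genes: list[str] | None = None          # explicit selection when clustering is off
    maternal_gene: str = "Bcat"
    target_times: tuple[float, ...] = (25.0, 50.0)
    n_runs: int = 100
    budget: int = 10000
    n_points: int = N_STANDARD_POINTS       # spatial points used in the fit
    threshold: float = network_inference.DEFAULT_THRESHOLD
    sensitivity_method: str = "fd"
    sensitivity_runs: int | None = None     # cap for the sensitivity stage

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.target_times = tuple(float(t) for t in cfg.target_times)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute cluster -> select -> build reference -> fit -> infer -> sens.

    Runs on fully synthetic inputs: a profile panel with the study's cluster
    shapes, and fitting targets simulated from the known demonstration
    circuit so ground-truth recovery can be checked.  All intermediates are
    written under ``config.out_dir``; every numerical stage derives its seed
    from the master seed, so reruns are byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict = {"config_digest": config.digest(), "seed": config.seed}

    profiles = synthetic_data.synthetic_profile_panel(config.seed,
                                                      config.profile_noise_sd)
    write_profiles(profiles, out / "profiles.tsv")
    logger.info("stage=synth profiles=%d", len(profiles))

    if config.run_clustering:
        result = clustering.cluster_profiles(profiles, config.cut_height)
        pd.DataFrame(result["distances"]).to_csv(out / "distances.tsv", sep="\t",
                                                 index=False)
        pd.DataFrame(result["linkage"],
                     columns=["left", "right", "height", "size"]
                     ).to_csv(out / "linkage.tsv", sep="\t", index=False)
        result["meta"].to_csv(out / "labels.tsv", sep="\t", index=False)
        names = [f"{p.gene}|{p.stage_hours:g}h|{k}" for k, p in enumerate(profiles)]
        (out / "dendrogram.nwk").write_text(
            clustering.to_newick(result["linkage"], names))
        domains = clustering.infer_cluster_domains(profiles, result["labels"])
        groups = clustering.build_gene_groups(result["meta"], domains)
        groups.to_csv(out / "gene_groups.tsv", sep="\t", index=False)
        reps = clustering.select_representatives(groups)
        selected = [reps[g] for g in sorted(reps)]
        artifacts["clusters"] = int(result["labels"].max())
        artifacts["representatives"] = selected
        logger.info("stage=cluster clusters=%d representatives=%s",
                    artifacts["clusters"], selected)
        interacting = [g for g in selected if g != config.maternal_gene][:3]
    else:
        if not config.genes:
            raise PipelineError("clustering disabled but no explicit gene list given")
        interacting = [g for g in config.genes if g != config.maternal_gene]
        artifacts["representatives"] = list(config.genes)
        logger.info("stage=cluster skipped (explicit gene list)")

    # reference data: maternal gradient plus targets simulated from the known
    # demonstration circuit over the selected interacting genes
    truth = synthetic_data.demo_gut_circuit(tuple(interacting))
    maternal_template = synthetic_data.make_template("maternal",
                                                     n_points=config.n_points)
    reference = synthetic_data.generate_reference_from_circuit(
        truth, maternal_template.values, (0.0,) + tuple(config.target_times),
        maternal_name=config.maternal_gene)
    reference.to_json(out / "reference.json")
    (out / "ground_truth_params.json").write_text(json.dumps(truth.to_dict()))
    logger.info("stage=reference genes=%s points=%d", interacting, config.n_points)

    fit_config = estimation.FitConfig(budget=config.budget, seed=config.seed)
    ensemble = estimation.run_ensemble(reference, fit_config, config.n_runs)
    ensemble.to_json(out / "ensemble.json")
    artifacts["best_objective"] = ensemble.best_run().best_value
    logger.info("stage=fit runs=%d best=%.4g", len(ensemble),
                artifacts["best_objective"])

    network = network_inference.infer_edges(ensemble, config.threshold)
    network.to_tsv(out / "network_edges.tsv")
    network.to_graphml(out / "network.graphml")
    network_inference.parameter_statistics(ensemble).to_csv(
        out / "parameter_statistics.tsv", sep="\t", index=False)
    artifacts["n_edges"] = len(network.edges)
    logger.info("stage=infer edges=%d threshold=%.2f", artifacts["n_edges"],
                config.threshold)

    sens_source = ensemble.param_sets()
    if config.sensitivity_runs:
        sens_source = sens_source[: config.sensitivity_runs]
    report = sensitivity.sensitivity_report(sens_source, reference,
                                            method=config.sensitivity_method)
    report.to_csv(out / "sensitivity.tsv", sep="\t", index=False)
    logger.info("stage=sens rows=%d", len(report))

    artifacts["elapsed_s"] = round(time.time() - t0, 2)
    (out / "summary.json").write_text(json.dumps(artifacts, indent=2, default=str))
    return artifacts
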