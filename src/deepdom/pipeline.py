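"""End-to-end orchestration of the analysis stages with a serializable
config and a JSON run report.

Stage order: simulate -> align -> assign -> preprocess -> metrics ->
ordinate -> network -> isotopes. Each stage reads its inputs from the
output directory when the producing stage is toggled off, so stages can
also be run one at a time (the CLI does exactly that).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import join_mass_lists, read_peaklist, remove_singletons
from .assignment import AnnotatedMatrix, AssignmentParams, assign_formulas
from .formulas import parse_formula
from .isotopes import spe_efficiency_by_group, load_water_chemistry
from .metrics import sample_summary_table
from .multivariate import bray_curtis, dbrda, nmds
from .network import interdomain_network, module_summary, write_edgelist, write_graphml
from .preprocessing import preprocess, read_grouping
from .synthetic import default_endmembers, generate_asv_table, generate_sample_peaklists, make_planted_modules

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "align", "assign", "preprocess", "metrics",
           "ordinate", "network", "isotopes")


@dataclass
class PipelineConfig:
    """All stage toggles, thresholds and paths of one pipeline run."""

    out_dir: str = "deepdom_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    # simulate
    n_samples: int = 15
    noise_cv: float = 0.1
    mass_error_ppm: float = 0.15
    n_asvs: int = 60
    n_planted_modules: int = 5
    latent_strength: float = 2.0
    asv_noise_sd: float = 0.2
    # align / assign
    tol_ppm: float = 0.5
    mdl: float = 3.0
    # preprocess
    min_occurrence: int = 3
    renormalize: bool = False
    grouping_path: str | None = None
    # metrics
    abios_path: str | None = None
    # ordinate
    k: int = 2
    n_starts: int = 20
    n_perm_ordination: int = 999
    # network
    min_samples: int = 5
    min_abundance: float = 0.001
    cutoff: float | None = 0.85
    n_perm_network: int = 100
    target_fdr: float = 0.05
    # isotopes
    water_chemistry_path: str | None = None

    def validate(self) -> None:
        if self.tol_ppm <= 0 or self.mdl < 0 or self.min_occurrence < 0:
            raise ValueError("invalid threshold in config")
        if self.cutoff is not None and not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must be in (0, 1]")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages and return (and write) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "stages": {s: bool(config.stages.get(s, False)) for s in _STAGES},
                    "counts": {}}
    on = report["stages"]

    try:
        if on["simulate"]:
            stage = "simulate"
            endmembers = default_endmembers(seed=config.seed)
            fractions = np.linspace(1.0, 0.0, config.n_samples)
            peaklists, chem, truth = generate_sample_peaklists(
                endmembers, fractions, mass_error_ppm=config.mass_error_ppm,
                noise_cv=config.noise_cv, seed=config.seed)
            pk_dir = out / "peaklists"
            pk_dir.mkdir(exist_ok=True)
            for pl in peaklists:
                pl.to_csv(pk_dir / f"{pl.sample_id}.csv")
            chem.to_csv(out / "chemistry.csv")
            truth.to_csv(out / "truth_intensities.csv")
            planted = make_planted_modules(n_modules=config.n_planted_modules,
                                           latent_strength=config.latent_strength)
            asv_table, asv_truth = generate_asv_table(
                config.n_asvs, config.n_samples, planted, seed=config.seed + 1,
                noise_sd=config.asv_noise_sd)
            asv_table.to_csv(out / "asv_table.tsv", sep="\t")
            asv_truth["mf_intensities"].to_csv(out / "truth_mf_block.csv")
            _write_json(out / "truth_links.json",
                        {"links": asv_truth["links"],
                         "member_module": asv_truth["member_module"]})
            report["counts"]["samples_simulated"] = int(config.n_samples)
            report["counts"]["peaks_per_sample_mean"] = float(
                np.mean([len(pl) for pl in peaklists]))

        if on["align"]:
            stage = "align"
            pk_dir = out / "peaklists"
            paths = sorted(pk_dir.glob("*.csv"))
            if not paths:
                raise FileNotFoundError(f"no peak lists under {pk_dir}")
            peaklists = [read_peaklist(p) for p in paths]
            aligned = join_mass_lists(peaklists, tol_ppm=config.tol_ppm)
            report["counts"]["features_after_join"] = aligned.n_features
            aligned = remove_singletons(aligned)
            report["counts"]["features_after_singleton_removal"] = aligned.n_features
            aligned.to_csv(out / "aligned_matrix.csv")
        else:
            aligned = None

        if on["assign"]:
            stage = "assign"
            if aligned is None:
                from .alignment import AlignedMatrix
                aligned = AlignedMatrix.from_csv(out / "aligned_matrix.csv",
                                                 tol_ppm=config.tol_ppm)
            params = AssignmentParams(tol_ppm=config.tol_ppm, mdl=config.mdl)
            annotated = assign_formulas(aligned, params)
            report["counts"].update({k: int(v) for k, v in annotated.filter_log.items()})
            annotated.to_tsv(out / "annotated_matrix.tsv")
        else:
            annotated = None

        if on["preprocess"]:
            stage = "preprocess"
            if annotated is None:
                annotated = AnnotatedMatrix.from_tsv(out / "annotated_matrix.tsv")
            grouping = read_grouping(config.grouping_path) if config.grouping_path else None
            processed = preprocess(annotated, min_occurrence=config.min_occurrence,
                                   renormalize=config.renormalize, grouping=grouping)
            report["counts"]["features_after_occurrence"] = int(len(processed.features))
            processed.to_tsv(out / "processed_matrix.tsv")
        else:
            processed = None

        if on["metrics"]:
            stage = "metrics"
            if processed is None:
                processed = AnnotatedMatrix.from_tsv(out / "processed_matrix.tsv")
            abios = ()
            if config.abios_path:
                abios = tuple(parse_formula(line.strip())
                              for line in Path(config.abios_path).read_text().splitlines()
                              if line.strip())
            summary = sample_summary_table(processed, abios)
            summary.to_csv(out / "sample_summaries.csv")
            report["counts"]["samples_summarized"] = int(len(summary))

        if on["ordinate"]:
            stage = "ordinate"
            if processed is None:
                processed = AnnotatedMatrix.from_tsv(out / "processed_matrix.tsv")
            chem = pd.read_csv(out / "chemistry.csv", index_col=0)
            d = bray_curtis(processed.intensities)
            ord_res = nmds(d, k=config.k, n_starts=config.n_starts, seed=config.seed)
            ord_res.coordinates.to_csv(out / "nmds_coordinates.csv")
            predictors = chem[[c for c in chem.columns
                               if c not in ("mixing_fraction", "DOC")]]
            rda = dbrda(d, predictors, n_perm=config.n_perm_ordination, seed=config.seed)
            _write_json(out / "ordination.json", {
                "nmds_stress": ord_res.stress,
                "nmds_converged": ord_res.converged,
                "dbrda_explained_fraction": rda.explained_fraction,
                "dbrda_pseudo_F": rda.pseudo_F,
                "dbrda_p_value": rda.p_value,
                "n_permutations": rda.n_permutations,
                "seed": config.seed,
            })

        if on["network"]:
            stage = "network"
            if processed is None:
                processed = AnnotatedMatrix.from_tsv(out / "processed_matrix.tsv")
            asv_table = pd.read_csv(out / "asv_table.tsv", sep="\t", index_col=0)
            mf = processed.intensities.copy()
            mf.index = pd.Index([f"feat{i:05d}" for i in range(len(mf))])
            truth_mf = out / "truth_mf_block.csv"
            if truth_mf.exists():
                block = pd.read_csv(truth_mf, index_col=0)
                if not block.empty:
                    mf = pd.concat([mf, block[mf.columns]])
            net = interdomain_network(mf, asv_table,
                                      min_samples=config.min_samples,
                                      min_abundance=config.min_abundance,
                                      cutoff=config.cutoff,
                                      n_perm=config.n_perm_network,
                                      target_fdr=config.target_fdr,
                                      seed=config.seed)
            write_graphml(net, out / "network.graphml")
            write_edgelist(net, out / "network_edges.tsv")
            module_summary(net).to_csv(out / "module_summary.csv", index=False)
            report["counts"].update({
                "network_nodes": net.n_nodes, "network_edges": net.n_edges,
                "network_modules": net.n_modules})
            report["network_modularity"] = None if np.isnan(net.modularity) else float(net.modularity)
            report["network_cutoff"] = net.cutoff
        else:
            report["counts"]["network_skipped"] = 1

        if on["isotopes"]:
            stage = "isotopes"
            table = load_water_chemistry(config.water_chemistry_path)
            eff = spe_efficiency_by_group(table)
            eff.to_csv(out / "spe_efficiency.csv")
            report["spe_efficiency"] = {g: round(float(r["mean"]), 4)
                                        for g, r in eff.iterrows()}
    except Exception as exc:  # noqa: BLE001 - re-raised with stage tag
        raise StageError(stage, exc) from exc

    _write_json(out / "run_report.json", report)
    return report
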