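"""End-to-end orchestration: simulate/load -> filter -> F_ST -> panel
selection -> forensic power -> assignment -> kinship screening.

:func:`run_pipeline` executes the stages in order, writes one artifact
set per stage into the output directory, and finishes with a manifest
(parameters, seed, package version, sha256 checksum per artifact).  All
randomness flows from the single config seed, so a rerun with the same
config reproduces identical artifacts and checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import dapc_classify, find_clusters_bic, loo_likelihood_assign, pca_genotypes
from .core import GenotypeMatrix, PanelforgeError, read_fixture, write_fixture
from .filtering import FilterConfig, apply_filter_cascade, read_bed_intervals
from .forensics import panel_power_summary
from .kinship import ParentageConfig, critical_delta
from .panels import search_reduced_subset, select_top_fst_panel
from .popgen import weir_cockerham_fst
from .synthetic import PopulationModel, generate_structured_populations

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either point ``vcf``/``metadata`` at existing inputs or leave them
    None to simulate a structured dataset (n_pops/fst_target/n_loci/
    n_per_pop).  ``seed`` drives every stochastic stage.
    """

    out_dir: str = "panelforge_run"
    vcf: str | None = None
    metadata: str | None = None
    repeat_bed: str | None = None
    # simulation settings (used when no vcf given)
    n_pops: int = 5
    fst_target: float = 0.2
    n_loci: int = 2000
    n_per_pop: int = 12
    # stage parameters
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    top_n: int = 50
    subset_size: int = 84
    subset_trials: int = 50
    assign_threshold: float = 0.8
    parentage: ParentageConfig = field(default_factory=ParentageConfig)
    seed: int = 0

    def validate(self) -> None:
        for p in (self.vcf, self.metadata, self.repeat_bed):
            if p is not None and not Path(p).exists():
                raise PanelforgeError(f"input file not found: {p}")
        if (self.vcf is None) != (self.metadata is None):
            raise PanelforgeError("vcf and metadata must be given together")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "setup"
    try:
        # --- inputs -------------------------------------------------------
        stage = "input"
        if config.vcf is None:
            model = PopulationModel(
                n_pops=config.n_pops,
                fst_target=config.fst_target,
                n_loci=config.n_loci,
                seed=config.seed,
            )
            gm, meta, _ = generate_structured_populations(model, config.n_per_pop)
            write_fixture(gm, meta, out / "input")
            artifacts += [out / "input.vcf", out / "input.meta.tsv"]
        else:
            from .core import read_metadata, read_vcf

            gm = read_vcf(config.vcf)
            meta = read_metadata(config.metadata)

        labels = meta.set_index("sample").loc[gm.samples, "pop"].to_numpy()

        # --- filtering ----------------------------------------------------
        stage = "filter"
        intervals = (
            read_bed_intervals(config.repeat_bed) if config.repeat_bed else None
        )
        gm_f, report = apply_filter_cascade(gm, config.filter_config, intervals)
        report_path = out / "filter_report.tsv"
        report.to_frame().to_csv(report_path, sep="\t", index=False)
        artifacts.append(report_path)
        keep_samples = set(gm_f.samples)
        labels = np.asarray(
            [l for s, l in zip(gm.samples, labels) if s in keep_samples]
        )

        # --- F_ST ---------------------------------------------------------
        stage = "fst"
        fst = weir_cockerham_fst(gm_f, labels)
        fst_path = out / "fst_pairwise.tsv"
        fst.summary().to_csv(fst_path, sep="\t", index=False)
        artifacts.append(fst_path)

        # --- panel selection ----------------------------------------------
        stage = "select"
        top_n = min(config.top_n, gm_f.n_loci // max(len(fst.pairs), 1) or 1)
        panel = select_top_fst_panel(fst, top_n=top_n)
        panel_path = out / "panel.tsv"
        panel.to_tsv(panel_path)
        artifacts.append(panel_path)

        subset_size = min(config.subset_size, len(panel))
        subset, score = search_reduced_subset(
            panel, gm_f, labels, size=subset_size,
            n_trials=config.subset_trials, seed=config.seed,
        )
        subset_path = out / "panel_subset.tsv"
        subset.to_tsv(subset_path)
        artifacts.append(subset_path)

        # --- forensic power -------------------------------------------------
        stage = "power"
        gm_panel = gm_f.take_loci(panel.locus_indices)
        power_table, power_summary = panel_power_summary(gm_panel)
        power_path = out / "locus_power.tsv"
        power_table.to_csv(power_path, sep="\t", index=False)
        summary_path = out / "panel_summary.json"
        summary_path.write_text(json.dumps(
            {"panel": power_summary, "subset_score": score}, indent=2, default=str
        ))
        artifacts += [power_path, summary_path]

        # --- assignment -----------------------------------------------------
        stage = "assign"
        scores, _, _ = pca_genotypes(
            gm_panel, n_components=min(20, gm_panel.n_samples - 1)
        )
        k, _ = find_clusters_bic(scores, k_max=min(8, gm_panel.n_samples - 1),
                                 seed=config.seed)
        _, reassign = dapc_classify(gm_panel, labels, n_pcs=10)
        loo = loo_likelihood_assign(gm_panel, labels,
                                    threshold=config.assign_threshold)
        assign_path = out / "assignments.tsv"
        loo.assignments.to_csv(assign_path, sep="\t", index=False)
        artifacts.append(assign_path)
        acc = float(
            (
                (loo.assignments["map_label"] == loo.assignments["true"])
                & loo.assignments["robust"]
            ).mean()
        )

        # --- kinship critical values ---------------------------------------
        stage = "kinship"
        freqs = gm_panel.alt_freq()
        ok = ~np.isnan(freqs)
        cfg = config.parentage
        strict, relaxed = critical_delta(freqs[ok], cfg, seed=config.seed)
        kin_path = out / "parentage_critical.json"
        kin_path.write_text(json.dumps(
            {"delta_strict": strict, "delta_relaxed": relaxed,
             "config": asdict(cfg)}, indent=2
        ))
        artifacts.append(kin_path)

        # --- manifest -------------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                k: v for k, v in asdict(config).items()
                if not isinstance(v, dict)
            },
            "chosen_k": k,
            "dapc_mean_reassignment": float(reassign.mean()),
            "loo_robust_accuracy": acc,
            "stages": [
                {"artifact": p.name, "sha256": _sha256(p)} for p in artifacts
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        flag = out / "FAILED"
        flag.write_text(f"stage={stage}\nerror={exc}\n")
        raise PanelforgeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
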