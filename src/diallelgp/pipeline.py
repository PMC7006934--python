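"""End-to-end experiment: simulate -> QC -> adjust -> predict -> GWAS.

``run_paper_experiment`` chains every stage of the hybrid-breeding analysis
on synthetic data and leaves a manifest (config snapshot, seeds, per-stage
counts, output checksums) beside the result tables, so identical configs
reproduce identical outputs for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simdata import SimConfig, simulate_parents, make_diallel, \
    simulate_phenotypes, line_phenotypes
from .genoqc import run_qc_pipeline
from .phenadj import adjust_both_regimes, heritability
from .predict import (McmcConfig, build_prediction_data, cross_validate,
                      METHODS)
from .gwas import (GwasConfig, build_null, scan, permutation_threshold,
                   select_model, significant_marker_h2)

PROFILES = {
    "desk": dict(n_parents_group1=20, n_parents_group2=12, n_markers=2000,
                 n_hybrids=400, n_qtl=120, cv_reps=10,
                 mcmc=dict(n_iter=3000, burn_in=500, thin=2),
                 n_perm=100, engine="reml"),
    "paper": dict(n_parents_group1=35, n_parents_group2=15, n_markers=34571,
                  n_hybrids=906, n_qtl=300, cv_reps=50,
                  mcmc=dict(n_iter=30000, burn_in=5000, thin=5),
                  n_perm=400, engine="gibbs"),
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def record(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, "time": time.time(), **counts})

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "seed": self.seed,
             "version": self.version, "stages": self.stages,
             "outputs": self.outputs}, indent=2, default=str))


def run_paper_experiment(out_dir, profile: str = "desk", seed: int = 0,
                         overrides: dict | None = None,
                         n_line_markers: int = 4) -> RunManifest:
    """Run the whole synthetic experiment and write result tables.

    Stages: simulate parents/diallel/phenotypes -> marker QC and in-silico
    hybrids -> adjusted means per N regime and LNTI -> parental-line GWAS to
    pick "significant" markers -> all prediction methods under replicated
    training-testing -> hybrid GWAS (A, AD and D configurations) with
    permutation threshold and per-marker heritabilities -> summary tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prof = dict(PROFILES[profile])
    if overrides:
        prof.update(overrides)
    cv_reps = prof.pop("cv_reps")
    mcmc_kw = prof.pop("mcmc")
    n_perm = prof.pop("n_perm")
    engine = prof.pop("engine")
    cfg = SimConfig(seed=seed, allow_intragroup=True, **prof)
    manifest = RunManifest(config={"profile": profile, **cfg.to_dict(),
                                   "cv_reps": cv_reps, "n_perm": n_perm,
                                   "engine": engine, "mcmc": mcmc_kw},
                           seed=seed, version=__version__)

    # --- simulate ---------------------------------------------------------
    parents = simulate_parents(cfg)
    design = make_diallel(parents, cfg.n_hybrids, seed=cfg.seed,
                          allow_intragroup=cfg.allow_intragroup)
    manifest.record("simulate_parents", n_parents=parents.n_samples,
                    n_markers=parents.n_markers, n_hybrids=design.n_hybrids)

    # --- QC and hybrids ---------------------------------------------------
    parents_qc, hybrids, qc_reports = run_qc_pipeline(parents, design,
                                                      seed=cfg.seed)
    pd.DataFrame([r.to_dict() for r in qc_reports]).to_csv(
        out / "qc_report.csv", index=False)
    manifest.register(out / "qc_report.csv")
    manifest.record("qc", n_markers_kept=hybrids.n_markers)

    plots, truth = simulate_phenotypes(hybrids, design, cfg)
    plots.to_csv(out / "plots.csv", index=False)
    truth.hybrids.to_csv(out / "true_values.csv", index=False)
    manifest.register(out / "plots.csv")
    manifest.register(out / "true_values.csv")
    manifest.record("simulate_phenotypes", n_plots=len(plots))

    # --- adjusted means and heritability ----------------------------------
    means, vcs = adjust_both_regimes(plots)
    means.table.to_csv(out / "adjusted_means.csv", index=False)
    manifest.register(out / "adjusted_means.csv")
    h2_rows = []
    for regime in ("LN", "IN"):
        h2p, h2e, vc = heritability(plots, regime=regime)
        h2_rows.append({"regime": regime, "h2_plot": h2p, "h2_entry": h2e,
                        **vc.to_dict()})
    pd.DataFrame(h2_rows).to_csv(out / "heritability.csv", index=False)
    manifest.register(out / "heritability.csv")
    manifest.record("adjust", n_hybrids=len(means.table))

    y = means.lnti.reindex(design.hybrid_ids).dropna()
    hyb_used = hybrids.take_samples(
        [hybrids.sample_ids.index(h) for h in y.index])

    # --- parental-line GWAS -> significant markers ------------------------
    line_vals = line_phenotypes(parents_qc, truth, cfg)
    line_cfg = GwasConfig(coding="A", kinship=("G_A",), n_pc=1,
                          n_perm=max(100, int(n_perm // 2)), seed=seed)
    line_null = build_null(line_vals.to_numpy(), parents_qc, line_cfg)
    line_scan = scan(line_vals.to_numpy(), parents_qc, line_cfg, line_null)
    line_thr = permutation_threshold(line_vals.to_numpy(), parents_qc,
                                     line_cfg, line_null)
    line_scan.threshold = line_thr
    sig = line_scan.significant["marker_id"].tolist()
    if len(sig) < n_line_markers:
        ranked = line_scan.table.nsmallest(n_line_markers, "p_A")
        sig = ranked["marker_id"].tolist()
    sig = [m for m in sig if m in set(hyb_used.marker_ids)][:max(
        n_line_markers, len(sig))]
    line_scan.table.to_csv(out / "line_gwas.csv", index=False)
    manifest.register(out / "line_gwas.csv")
    manifest.record("line_gwas", n_significant=len(sig),
                    threshold=line_thr)

    # --- prediction -------------------------------------------------------
    data = build_prediction_data(hyb_used, sig)
    mcmc = McmcConfig(seed=seed, **mcmc_kw)
    yv = y.to_numpy()
    cv_rows = []
    for method in METHODS:
        if method.startswith("mas") and data.partition.n_significant == 0:
            manifest.record("cv_skip", method=method,
                            reason="no significant markers")
            continue
        res = cross_validate(yv, data, method, n_reps=cv_reps, seed=seed,
                             engine=engine, mcmc=mcmc)
        cv_rows.append(res.summary())
        pd.DataFrame({"replicate": np.arange(res.n_reps),
                      "pearson_r": res.replicates}).to_csv(
            out / f"cv_{method}.csv", index=False)
        manifest.register(out / f"cv_{method}.csv")
    cv_summary = pd.DataFrame(cv_rows)
    cv_summary.to_csv(out / "cv_summary.csv", index=False)
    manifest.register(out / "cv_summary.csv")
    manifest.record("cross_validation", n_methods=len(cv_rows))

    # --- hybrid GWAS ------------------------------------------------------
    gwas_rows = []
    candidates = []
    for coding, kin in (("A", ("G_A",)), ("AD", ("G_A",)), ("D", ("G_D",))):
        cfgs = [GwasConfig(coding=coding, kinship=kin, n_pc=npc,
                           n_perm=n_perm, seed=seed) for npc in (0, 1)]
        scans = []
        for c in cfgs:
            null = build_null(yv, hyb_used, c)
            scans.append(scan(yv, hyb_used, c, null))
            scans[-1]._null = null
        best = select_model(scans)
        thr = permutation_threshold(yv, hyb_used, best.config, best._null)
        best.threshold = thr
        best.table.to_csv(out / f"hybrid_gwas_{coding}.csv", index=False)
        manifest.register(out / f"hybrid_gwas_{coding}.csv")
        h2tab = significant_marker_h2(best, yv)
        if not h2tab.empty:
            h2tab["scan"] = coding
            gwas_rows.append(h2tab)
        candidates.append(best)
        manifest.record(f"hybrid_gwas_{coding}", threshold=thr,
                        lambda_gc=best.lambda_gc,
                        n_significant=len(best.significant))
    if gwas_rows:
        pd.concat(gwas_rows).to_csv(out / "marker_h2.csv", index=False)
        manifest.register(out / "marker_h2.csv")

    # --- line vs hybrid overlap -------------------------------------------
    hybrid_sig = set()
    for b in candidates:
        hybrid_sig |= set(b.significant["marker_id"])
    overlap = sorted(hybrid_sig & set(sig))
    summary = {"line_significant": sig, "hybrid_significant": sorted(hybrid_sig),
               "overlap": overlap,
               "cv_summary": cv_rows, "heritability": h2_rows}
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=str))
    manifest.register(out / "summary.json")
    manifest.record("summary", n_overlap=len(overlap))
    manifest.write(out / "manifest.json")
    return manifest
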