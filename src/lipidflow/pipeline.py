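"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes simulate -> preprocess -> tableone -> sov ->
differential -> networks (case, control, combined) -> enrichment ->
classifier -> causality on either a synthetic cohort or TSV inputs,
writing every intermediate artifact as plain text (TSV/JSON/YAML) and
emitting a machine-readable run report with per-stage parameters,
artifact checksums and summary statistics.  Identical configurations
produce identical checksums.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import causality as causal_mod
from . import classifier as clf_mod
from . import network as net_mod
from .cohort_stats import table_one
from .containers import (read_clinical, read_lipid_matrix,
                         write_json, write_lipid_matrix)
from .differential import (confounder_free_subset, dual_cohort_intersect,
                           fit_moderated)
from .enrichment import class_enrichment
from .preprocess import preprocess
from .simulate import SimConfig, inject_missingness, simulate_cohort, write_cohort
from .sov import screen_lipids, sov_decompose

log = logging.getLogger("lipidflow")


@dataclass
class RunConfig:
    """One pipeline run.

    Either ``simulate`` is set (a :class:`SimConfig`) or ``input_prefix``
    and ``clinical_path`` point at on-disk TSVs.  Stage parameters default
    to the reference study's printed values: differential alpha 0.01, TOM
    edge cut 0.5, connectivity delta 5, information-gain cut 0.1, 80/20
    split repeated 10 times with base seed 1996, causality alpha 0.05.
    """
    outdir: str = "lipidflow_run"
    simulate: SimConfig | None = field(default_factory=SimConfig)
    input_prefix: str | None = None
    clinical_path: str | None = None
    knn_k: int = 10
    log_base: float = 2.0
    sov_factors: list | None = None        # None = all clinical columns
    screen_threshold: float = 1.0
    diff_alpha: float = 0.01
    subset_exclude: dict = field(default_factory=lambda: {
        "smoker": "yes", "gestational_diabetes": "yes"})
    network: net_mod.NetworkConfig = field(default_factory=net_mod.NetworkConfig)
    ig_cut: float = 0.1
    train_frac: float = 0.8
    repeats: int = 10
    cv_folds: int = 10
    classifier_model: str = "random_forest"
    classifier_seed: int = 1996
    causality_alpha: float = 0.05
    causality_lag: int = 1
    order_by: str = "gestational_age"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("simulate") is not None:
            sim = dict(d["simulate"])
            if "modules" in sim:
                from .simulate import ModuleSpec
                sim["modules"] = [ModuleSpec(**m) for m in sim["modules"]]
            d["simulate"] = SimConfig(**sim)
        if "network" in d:
            d["network"] = net_mod.NetworkConfig(**d["network"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Report:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.stages = []

    def stage(self, name):
        report = self
        class _Ctx:
            def __enter__(ctx):
                ctx.t0 = time.perf_counter()
                ctx.entry = {"name": name, "artifacts": {}, "summary": {}}
                log.info("stage %s: start", name)
                return ctx
            def add(ctx, *paths):
                for p in paths:
                    p = Path(p)
                    ctx.entry["artifacts"][str(p.relative_to(report.outdir))] = _sha256(p)
            def summarize(ctx, **kv):
                ctx.entry["summary"].update(kv)
            def __exit__(ctx, exc_type, exc, tb):
                if exc is not None:
                    log.error("stage %s: FAILED (%s)", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                ctx.entry["seconds"] = round(time.perf_counter() - ctx.t0, 3)
                report.stages.append(ctx.entry)
                log.info("stage %s: done in %.1fs", name, ctx.entry["seconds"])
        return _Ctx()


def validate_inputs(config: RunConfig) -> None:
    """Fail fast before any stage runs."""
    if config.simulate is None:
        if not config.input_prefix or not config.clinical_path:
            raise ValueError("need either a simulation config or input paths")
        clinical = read_clinical(config.clinical_path)
    else:
        config.simulate.validate()
        return
    required = ["status", config.order_by]
    missing = [c for c in required if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table lacks required columns: {missing}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    validate_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = _Report(outdir)
    truth = None

    with report.stage("simulate") as st:
        if config.simulate is not None:
            sim = config.simulate
            matrix, clinical, truth = simulate_cohort(sim)
            if sim.missing_rate > 0:
                matrix = inject_missingness(matrix, sim.missing_rate,
                                            sim.censoring_steepness, seed=sim.seed)
            paths = write_cohort(matrix, clinical, truth, sim, outdir / "cohort")
            st.add(*paths.values())
            st.summarize(n_samples=matrix.n_samples, n_lipids=matrix.n_lipids,
                         missing_fraction=float(matrix.values.isna().mean().mean()))
        else:
            matrix = read_lipid_matrix(config.input_prefix)
            clinical = read_clinical(config.clinical_path)
            st.summarize(n_samples=matrix.n_samples, n_lipids=matrix.n_lipids,
                         source="disk")

    with report.stage("preprocess") as st:
        matrix = preprocess(matrix, k=config.knn_k, log_base=config.log_base)
        paths = write_lipid_matrix(matrix, outdir / "preprocessed")
        st.add(*paths.values())
        st.summarize(scale_state=matrix.scale_state)

    with report.stage("tableone") as st:
        t1 = table_one(clinical, group_var="status")
        p = outdir / "table_one.tsv"
        t1.to_csv(p, sep="\t")
        st.add(p)
        st.summarize(n_variables=len(t1))

    with report.stage("sov") as st:
        factors = config.sov_factors or [c for c in clinical.columns]
        sov = sov_decompose(matrix, clinical, factors)
        screened = screen_lipids(sov, "status", config.screen_threshold)
        p1 = outdir / "sov_f.tsv"; sov.F.to_csv(p1, sep="\t")
        p2 = outdir / "screened_lipids.tsv"
        pd.Series(screened, name="lipid").to_csv(p2, sep="\t", index=False)
        st.add(p1, p2)
        st.summarize(n_screened=len(screened), factor_ranking=sov.ranking)
        confounders = [f for f in sov.ranking
                       if f != "status" and sov.F[f].mean() > 1.0]
        from ._design import prune_aliased
        kept, dropped = prune_aliased(clinical, ["status"] + confounders)
        confounders = [c for c in kept if c != "status"]
        if dropped:
            st.summarize(aliased_confounders_dropped=dropped)
        screened_matrix = matrix.subset_lipids(screened)

    with report.stage("differential") as st:
        full = fit_moderated(screened_matrix, clinical, confounders,
                             alpha=config.diff_alpha)
        subset_ids = confounder_free_subset(clinical, config.subset_exclude)
        sub_clin = clinical.loc[subset_ids]
        sub_conf = [c for c in confounders if sub_clin[c].nunique() > 1]
        sub_conf = [c for c in prune_aliased(sub_clin, ["status"] + sub_conf)[0]
                    if c != "status"]
        sub = fit_moderated(screened_matrix.subset_samples(subset_ids),
                            sub_clin, sub_conf,
                            alpha=config.diff_alpha)
        final = dual_cohort_intersect(full, sub, alpha=config.diff_alpha)
        p1 = outdir / "differential_full.tsv"; full.table.to_csv(p1, sep="\t")
        p2 = outdir / "differential_subset.tsv"; sub.table.to_csv(p2, sep="\t")
        p3 = outdir / "differential_final.tsv"; final.to_csv(p3, sep="\t")
        st.add(p1, p2, p3)
        st.summarize(n_significant_full=int(full.table["significant"].sum()),
                     n_significant_subset=int(sub.table["significant"].sum()),
                     n_final=len(final), final_lipids=final.index.tolist())

    def run_one_network(name, m, b):
        net = net_mod.build_network(m, b)
        net_mod.detect_modules(net, m, config.network)
        pm = outdir / f"modules_{name}.tsv"
        net.modules.to_csv(pm, sep="\t")
        pe = outdir / f"edges_{name}.tsv"
        net_mod.edge_list(net, config.network.edge_retention_tom) \
               .to_csv(pe, sep="\t", index=False)
        return net, (pm, pe)

    def densities_of(net):
        return {m: net_mod.module_density(net, m)
                for m in sorted(set(net.modules) - {"grey"})
                if (net.modules == m).sum() > 1}

    with report.stage("network_conditions") as st:
        from ._design import prune_aliased as _prune
        all_covs = [c for c in clinical.columns if c != "status"]
        net_covs = [c for c in _prune(clinical, ["status"] + all_covs)[0]
                    if c != "status"]
        adjusted = net_mod.adjust_for_confounders(screened_matrix, clinical,
                                                  keep="status",
                                                  confounders=net_covs)
        case_ids = clinical.index[clinical["status"] == 1]
        ctrl_ids = clinical.index[clinical["status"] == 0]
        case_m = adjusted.subset_samples(case_ids)
        ctrl_m = adjusted.subset_samples(ctrl_ids)
        if config.network.power is None:
            beta = max(net_mod.pick_soft_threshold(case_m, rsq_cut=config.network.rsq_cut),
                       net_mod.pick_soft_threshold(ctrl_m, rsq_cut=config.network.rsq_cut))
        else:
            beta = config.network.power
        net_case, paths_c = run_one_network("case", case_m, beta)
        net_ctrl, paths_k = run_one_network("control", ctrl_m, beta)
        st.add(*paths_c, *paths_k)
        increased, decreased, dk = net_mod.connectivity_diff(
            net_case, net_ctrl, config.network.connectivity_delta)
        pk = outdir / "connectivity_diff.tsv"; dk.to_csv(pk, sep="\t")
        overlap = net_mod.module_overlap(net_ctrl.modules, net_case.modules)
        po = outdir / "module_overlap.tsv"; overlap.to_csv(po, sep="\t", index=False)
        st.add(pk, po)
        st.summarize(beta=beta, n_increased=len(increased),
                     n_decreased=len(decreased),
                     module_densities={"case": densities_of(net_case),
                                       "control": densities_of(net_ctrl)})

    with report.stage("network_combined") as st:
        if config.network.power is None:
            beta_comb = net_mod.pick_soft_threshold(
                adjusted, rsq_cut=config.network.rsq_cut)
        else:
            beta_comb = config.network.power
        net_comb, paths = run_one_network("combined", adjusted, beta_comb)
        st.add(*paths)
        assoc = net_mod.module_trait_association(net_comb, clinical["status"]) \
            if net_comb.eigenlipids.shape[1] else pd.DataFrame()
        pa = outdir / "module_trait.tsv"; assoc.to_csv(pa, sep="\t")
        st.add(pa)
        st.summarize(beta_combined=beta_comb,
                     module_densities=densities_of(net_comb))

    with report.stage("enrichment") as st:
        universe = screened_matrix.lipid_ids.tolist()
        classes = screened_matrix.lipid_classes
        outputs = {}
        for name, members in (("increased_connectivity", increased),
                              ("decreased_connectivity", decreased),
                              ("differential_final", final.index.tolist())):
            if members:
                enr = class_enrichment(members, universe, classes)
                pth = outdir / f"enrichment_{name}.tsv"
                enr.to_csv(pth, sep="\t")
                st.add(pth)
                sig = enr.index[enr["p"] < 0.05].tolist()
                outputs[name] = sig
        st.summarize(significant_classes=outputs)

    with report.stage("classifier") as st:
        feats = final.index.tolist()
        if len(feats) < 2:
            feats = full.table["p"].nsmallest(5).index.tolist()
            st.summarize(note="fewer than 2 final lipids; using top-5 by p")
        rep = clf_mod.train_evaluate(
            matrix.values, clinical["status"], candidates=feats,
            train_frac=config.train_frac, repeats=config.repeats,
            cv_folds=config.cv_folds, model=config.classifier_model,
            seed=config.classifier_seed, ig_cut=config.ig_cut)
        other = pd.DataFrame({
            c: (clinical[c].astype(str) == "yes").astype(int)
            for c in ("gestational_diabetes", "chronic_hypertension")
            if c in clinical.columns})
        spec = clf_mod.specificity_check(rep, matrix.values, other) \
            if len(other.columns) else pd.DataFrame()
        p1 = outdir / "classifier_metrics.tsv"; rep.aggregate.to_csv(p1, sep="\t")
        p2 = outdir / "classifier_importances.tsv"
        rep.importances.rename("importance").to_csv(p2, sep="\t")
        p3 = outdir / "classifier_specificity.tsv"; spec.to_csv(p3, sep="\t")
        st.add(p1, p2, p3)
        st.summarize(f1=rep.metric("f1")[0],
                     balanced_accuracy=rep.metric("balanced_accuracy")[0],
                     auroc=rep.metric("auroc")[0])

    with report.stage("causality") as st:
        lipids = final.index.tolist()
        if len(lipids) < 2:
            lipids = full.table["p"].nsmallest(5).index.tolist()
        graph = causal_mod.causal_graph(
            matrix, clinical, lipids, outcome="status",
            order_by=config.order_by, alpha=config.causality_alpha,
            lag=config.causality_lag)
        p1 = graph.write_edges(outdir / "causal_edges.tsv")
        st.add(p1)
        st.summarize(n_edges=len(graph.edges), mediators=graph.mediators)

    run_report = {
        "n_stages": len(report.stages),
        "stages": report.stages,
        "parameters": {
            "diff_alpha": config.diff_alpha,
            "edge_retention_tom": config.network.edge_retention_tom,
            "connectivity_delta": config.network.connectivity_delta,
            "ig_cut": config.ig_cut,
            "train_frac": config.train_frac,
            "repeats": config.repeats,
            "classifier_seed": config.classifier_seed,
            "causality_alpha": config.causality_alpha,
        },
    }
    write_json(run_report, outdir / "run_report.json")
    return run_report
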