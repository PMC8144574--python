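"""End-to-end orchestration.

Runs the full dimension-resolved analysis — synthetic cohort (or supplied
matrices) -> filtering -> gene / isoform / AS differential expression for
total PCL and the four symptom dimensions -> post-hoc curve clustering ->
cross-dimension comparison -> GSEA — writing every table as TSV/JSON plus a
manifest with config, checksums and per-stage wall clock.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, compare, gsea, io, splicing, synthetic
from .nbgam import SmoothSpec, estimate_size_factors, filter_low_counts, run_de
from .synthetic import COVARIATE_COLUMNS, DIMENSIONS, CohortSpec

log = logging.getLogger("dimex")

PHENOTYPES = ("total_pcl",) + DIMENSIONS


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; YAML-serializable."""

    output_dir: str = "dimex_out"
    # either a synthetic cohort spec ...
    synthetic: CohortSpec | None = field(default_factory=CohortSpec)
    # ... or paths to user-supplied inputs
    counts_path: str | None = None
    tpm_path: str | None = None
    ioe_path: str | None = None
    phenotypes_path: str | None = None
    gmt_path: str | None = None

    fdr_gene: float = 0.05
    fdr_gsea: float = 0.1
    unique_other_p: float = 0.1
    edf_nonlinear: float = 1.5
    min_set: int = 15
    max_set: int = 500
    min_mean_count: float = 5.0
    min_mean_tpm: float = 1.0
    n_perm: int = 1000
    gap_k_max: int = 8
    gap_n_reference: int = 50
    n_basis: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("fdr_gene", "fdr_gsea", "unique_other_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.edf_nonlinear <= 1.0:
            raise ValueError("edf_nonlinear must exceed 1")

    @property
    def smooth_spec(self) -> SmoothSpec:
        return SmoothSpec(n_basis=self.n_basis)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        syn = raw.pop("synthetic", "default")
        cfg = cls(**raw)
        if syn is None:
            cfg.synthetic = None
        elif isinstance(syn, dict):
            cfg.synthetic = CohortSpec(**syn)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(counts=None, tpm=None, catalog=None, phenotypes=None
                    ) -> list[str]:
    """Cross-check sample-id and transcript-id concordance; returns issues."""
    issues: list[str] = []
    if phenotypes is None:
        return ["no phenotype table provided"]
    samples = set(phenotypes.index)
    for name, mat in (("counts", counts), ("tpm", tpm)):
        if mat is None:
            continue
        missing = [s for s in mat.columns if s not in samples]
        for s in missing:
            issues.append(f"{name} sample {s!r} missing from phenotype table")
        absent = [s for s in phenotypes.index if s not in set(mat.columns)]
        for s in absent:
            issues.append(f"phenotype sample {s!r} missing from {name} matrix")
    missing_cols = [c for c in ("total_pcl",) + DIMENSIONS
                    if c not in phenotypes.columns]
    for c in missing_cols:
        issues.append(f"phenotype table lacks column {c!r}")
    if catalog is not None and tpm is not None:
        known = set(tpm.index)
        for event_id, row in catalog.iterrows():
            tr = set(str(row["total_transcripts"]).split(","))
            unknown = tr - known
            if unknown:
                issues.append(
                    f"event {event_id} references unknown transcripts "
                    f"{sorted(unknown)}")
    return issues


def _random_gene_sets(gene_ids, rng: np.random.Generator, n_sets: int = 40,
                      min_size: int = 15, max_size: int = 60
                      ) -> dict[str, list[str]]:
    """Random GMT collection over the analysis universe (synthetic mode)."""
    ids = list(gene_ids)
    sets = {}
    for j in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        size = min(size, len(ids))
        members = list(rng.choice(ids, size=size, replace=False))
        sets[f"SET_{j:03d}"] = members
    return sets


class Manifest:
    def __init__(self, config: PipelineConfig):
        self.data = {"config": config.to_dict(), "stages": {}, "outputs": {}}

    def stage(self, name: str, seconds: float, **info):
        self.data["stages"][name] = {"seconds": round(seconds, 3), **info}

    def output(self, path: Path):
        self.data["outputs"][path.name] = _sha256(path)

    def write(self, path: Path):
        path.write_text(json.dumps(self.data, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict.

    Deterministic given the config seeds; aborts with the failing stage
    named if any stage raises.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    rng = np.random.default_rng(config.seed)
    spec = config.smooth_spec

    def _save(df: pd.DataFrame, name: str):
        path = out / name
        io.write_matrix(df, path)
        manifest.output(path)

    stage = "inputs"
    try:
        t0 = time.perf_counter()
        if config.synthetic is not None:
            syn = config.synthetic
            phenotypes = synthetic.generate_phenotypes(syn)
            gene_truth = synthetic.generate_truth(syn, syn.n_genes, "gene", 11)
            iso_truth = synthetic.generate_truth(syn, syn.n_isoforms, "iso", 12)
            ev_truth = synthetic.generate_truth(syn, syn.n_events, "ev", 13)
            counts = synthetic.generate_counts(syn, phenotypes, gene_truth)
            tpm = synthetic.generate_isoform_tpm(syn, phenotypes, iso_truth)
            catalog, ev_tpm = synthetic.generate_psi_truth(syn, phenotypes,
                                                           ev_truth)
            gene_sets = _random_gene_sets(counts.index, rng)
            _save(phenotypes, "phenotypes.tsv")
            _save(counts, "counts.tsv")
            _save(tpm, "isoform_tpm.tsv")
            _save(ev_tpm, "event_tpm.tsv")
            for df, name in ((gene_truth, "truth_genes.tsv"),
                             (iso_truth, "truth_isoforms.tsv"),
                             (ev_truth, "truth_events.tsv")):
                _save(df, name)
            io.write_ioe(catalog, out / "events.ioe")
            manifest.output(out / "events.ioe")
            io.write_gmt(gene_sets, out / "gene_sets.gmt")
            manifest.output(out / "gene_sets.gmt")
        else:
            counts = io.read_matrix(config.counts_path) if config.counts_path else None
            tpm = io.read_matrix(config.tpm_path, "transcript_id") if config.tpm_path else None
            catalog = io.read_ioe(config.ioe_path) if config.ioe_path else None
            phenotypes = io.read_phenotypes(config.phenotypes_path)
            ev_tpm = tpm
            gene_sets = io.read_gmt(config.gmt_path) if config.gmt_path else {}
        issues = validate_inputs(counts, ev_tpm if config.synthetic is not None else tpm,
                                 catalog, phenotypes)
        if issues:
            raise ValueError("input validation failed: " + "; ".join(issues))
        covariates = phenotypes.loc[:, list(COVARIATE_COLUMNS)]
        manifest.stage(stage, time.perf_counter() - t0)

        # --- gene-level DE, all phenotypes ---------------------------------
        stage = "de_genes"
        t0 = time.perf_counter()
        counts_f = filter_low_counts(counts, config.min_mean_count, log)
        size_factors = estimate_size_factors(counts_f)
        gene_results: dict[str, pd.DataFrame] = {}
        gene_curves: dict[str, pd.DataFrame] = {}
        for ph in PHENOTYPES:
            res, curves = run_de(counts_f, phenotypes[ph], covariates, spec,
                                 size_factors=size_factors,
                                 alpha=config.fdr_gene,
                                 edf_nonlinear=config.edf_nonlinear)
            gene_results[ph] = res
            gene_curves[ph] = curves
            _save(res, f"de_genes_{ph}.tsv")
            _save(curves, f"curves_genes_{ph}.tsv")
        manifest.stage(stage, time.perf_counter() - t0,
                       n_genes_tested=len(counts_f))

        # --- isoform-level DE ----------------------------------------------
        stage = "de_isoforms"
        t0 = time.perf_counter()
        iso_results = {}
        if tpm is not None:
            tpm_f = splicing.filter_low_tpm(tpm, config.min_mean_tpm, log)
            logtpm = splicing.transform_isoforms(tpm_f)
            for ph in PHENOTYPES:
                res, _ = splicing.run_continuous_de(
                    logtpm, phenotypes[ph], covariates, spec,
                    alpha=config.fdr_gene,
                    edf_nonlinear=config.edf_nonlinear)
                iso_results[ph] = res
                _save(res, f"de_isoforms_{ph}.tsv")
        manifest.stage(stage, time.perf_counter() - t0,
                       n_isoforms_tested=len(iso_results.get("total_pcl", ())))

        # --- AS-level DE ----------------------------------------------------
        stage = "de_events"
        t0 = time.perf_counter()
        event_results = {}
        if catalog is not None:
            psi = splicing.compute_psi_matrix(catalog, ev_tpm)
            psi_logit = splicing.logit_psi(psi)
            _save(psi, "psi_ori.tsv")
            _save(psi_logit, "psi_logit.tsv")
            for ph in PHENOTYPES:
                res, _ = splicing.run_continuous_de(
                    psi_logit, phenotypes[ph], covariates, spec,
                    alpha=config.fdr_gene,
                    edf_nonlinear=config.edf_nonlinear)
                event_results[ph] = res
                _save(res, f"de_events_{ph}.tsv")
        manifest.stage(stage, time.perf_counter() - t0,
                       n_events_tested=len(event_results.get("total_pcl", ())))

        # --- post-hoc clustering of nonlinear total-PCL genes ---------------
        stage = "cluster"
        t0 = time.perf_counter()
        total = gene_results["total_pcl"]
        nonlin_ids = list(total.index[total["nonlinear"].fillna(False)])
        cluster_info = {"n_nonlinear": len(nonlin_ids)}
        if len(nonlin_ids) >= 2:
            curve_set = clustering.extract_curves(gene_curves["total_pcl"],
                                                  nonlin_ids)
            gres = clustering.gap_statistic(curve_set,
                                            k_max=min(config.gap_k_max,
                                                      len(nonlin_ids)),
                                            n_reference=config.gap_n_reference,
                                            seed=config.seed)
            _save(gres.assignments_frame(), "cluster_assignments.tsv")
            gap_df = pd.DataFrame({"k": np.arange(1, len(gres.gap) + 1),
                                   "gap": gres.gap, "se": gres.gap_se}
                                  ).set_index("k")
            _save(gap_df, "gap_curve.tsv")
            means = pd.DataFrame(gres.cluster_means,
                                 index=pd.Index(range(gres.k_optimal),
                                                name="cluster"),
                                 columns=gene_curves["total_pcl"].columns)
            _save(means, "cluster_mean_curves.tsv")
            cluster_info["k_optimal"] = gres.k_optimal
        manifest.stage(stage, time.perf_counter() - t0, **cluster_info)

        # --- cross-dimension comparison -------------------------------------
        stage = "compare"
        t0 = time.perf_counter()
        for level, tables in (("genes", gene_results),
                              ("isoforms", iso_results),
                              ("events", event_results)):
            if not tables:
                continue
            dims_only = compare.MultiDimResults(
                {d: tables[d] for d in DIMENSIONS})
            uniq_rows = []
            for d in DIMENSIONS:
                for f in compare.call_unique(dims_only, d, config.fdr_gene,
                                             config.unique_other_p):
                    uniq_rows.append({"dimension": d, "feature_id": f})
            uniq = pd.DataFrame(uniq_rows,
                                columns=["dimension", "feature_id"])
            path = out / f"unique_{level}.tsv"
            uniq.to_csv(path, sep="\t", index=False)
            manifest.output(path)
            _save(compare.neglogp_correlation(dims_only),
                  f"neglogp_correlation_{level}.tsv")
            _save(compare.overlap_counts(dims_only, config.fdr_gene)
                  .to_frame(), f"venn_regions_{level}.tsv")
            thresholds = (1e-4, 1e-3, 0.01, 0.05, 0.1)
            _save(compare.significance_curves(dims_only, thresholds),
                  f"threshold_curves_{level}.tsv")
        if event_results and catalog is not None:
            types = catalog["event_type"]
            background = types.value_counts(normalize=True).to_dict()
            prop_tests = {}
            for ph in PHENOTYPES:
                res = event_results[ph]
                sig = res.index[(res["fdr"] < config.fdr_gene).fillna(False)]
                observed = types.loc[types.index.intersection(sig)]\
                    .value_counts().to_dict()
                if observed and sum(observed.values()) >= 1:
                    try:
                        prop_tests[ph] = compare.as_proportion_test(
                            observed, background)
                    except ValueError as exc:
                        prop_tests[ph] = {"error": str(exc)}
            path = out / "as_proportion_tests.json"
            path.write_text(json.dumps(prop_tests, indent=2))
            manifest.output(path)
        manifest.stage(stage, time.perf_counter() - t0)

        # --- GSEA ------------------------------------------------------------
        stage = "gsea"
        t0 = time.perf_counter()
        gsea_results = {}
        if gene_sets:
            for ph in PHENOTYPES:
                ranking = gsea.build_ranking(gene_results[ph])
                filtered = gsea.filter_sets(gene_sets, ranking,
                                            config.min_set, config.max_set)
                if not filtered:
                    continue
                table = gsea.significance(ranking, filtered,
                                          n_perm=config.n_perm,
                                          seed=config.seed,
                                          fdr_threshold=config.fdr_gsea)
                gsea_results[ph] = table
                _save(table, f"gsea_{ph}.tsv")
            dim_tables = {d: gsea_results[d] for d in DIMENSIONS
                          if d in gsea_results}
            if len(dim_tables) == len(DIMENSIONS):
                rows = []
                for d in DIMENSIONS:
                    for s in gsea.call_unique_sets(dim_tables, d,
                                                   config.fdr_gsea,
                                                   other_p_threshold=config.unique_other_p):
                        rows.append({"dimension": d, "set_name": s})
                uniq = pd.DataFrame(rows, columns=["dimension", "set_name"])
                path = out / "unique_gene_sets.tsv"
                uniq.to_csv(path, sep="\t", index=False)
                manifest.output(path)
        manifest.stage(stage, time.perf_counter() - t0)
    except Exception as exc:
        manifest.data["failed_stage"] = stage
        manifest.data["error"] = str(exc)
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest.data
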