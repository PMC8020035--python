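"""End-to-end orchestration of the paired urinary-metabolomics analysis.

Stage order mirrors the standard paired-cohort workflow: spectra are
aligned, binned and integrated; the bin table is normalized to the total
metabolome (water/urea regions excluded), log-transformed and
pareto-scaled; every bin is paired-tested between timepoints; VIAVC ranks
bins and picks the best discriminating subset; the union of
univariate-significant bins and the VIAVC best subset feeds PCA, OPLS-DA
(with double cross-validation and permutation testing) and the clustering
heat-map order; the best subset is evaluated by ROC; the top F-ranked bins
enter the Bonferroni-screened clinical correlation; and the significant
bins, mapped to pathway compounds, are screened for over-representation
and topology impact.

Every stage reads and writes only documented CSV/JSON artifacts in the run
directory, so stages are independently re-runnable; a provenance manifest
records stage order, seeds and the parameter hash. A full run is a pure
function of (config, seed): deleting the run directory and re-running
reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import pathways as pw
from ._plscv import cv_plsda_scores, make_splits
from .models import (OPLSDA, _encode_labels, double_cv_q2,
                     hierarchical_heatmap_order, pca, permutation_test)
from .preprocess import ProcessedMatrix, load_processed, preprocess
from .roc import bootstrap_ci, panel_accuracy, roc_curve
from .simulate import PeakLibrary, default_library
from .spectra import (BinSet, BinTable, Spectrum, adaptive_bin,
                      align_to_reference, apply_manual_edits, exclude_regions,
                      integrate, mean_spectrum)
from .univariate import test_all_bins
from .viavc import VIAVCResult, VIAVCSelector

logger = logging.getLogger("uromet")

STAGES = [
    "spectral_processing",
    "preprocessing",
    "univariate_stats",
    "viavc_selection",
    "multivariate_models",
    "biomarker_roc",
    "clinical_correlation",
    "pathway_analysis",
]


@dataclass
class RunConfig:
    """All paths and stage parameters of one analysis run."""

    spectra_dir: str = ""
    clinical_csv: str = ""
    peak_library_csv: str | None = None  # None -> bundled default library
    pathway_json: str | None = None  # None -> bundled default fixture
    out_dir: str = "uromet_run"
    # spectral processing
    align: bool = True
    max_shift: float = 0.03
    min_segment: int = 64
    min_width: float = 0.02
    noise_threshold: float | None = None
    smooth_window: int = 11
    water_region: tuple = (4.5, 5.0)
    urea_region: tuple = (5.5, 6.0)
    manual_edits: list = field(default_factory=list)
    # statistics
    alpha: float = 0.05
    alpha_normality: float = 0.05
    n_perm: int = 2000
    n_boot: int = 2000
    folds: int = 10
    max_orthogonal: int = 3
    # viavc
    viavc_rows: int = 500
    inclusion_prob: float = 0.5
    max_k: int = 10
    top_f_ranked: int = 19
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["water_region"] = list(self.water_region)
        d["urea_region"] = list(self.urea_region)
        d["manual_edits"] = [list(e) for e in self.manual_edits]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["water_region"] = tuple(d.get("water_region", (4.5, 5.0)))
        d["urea_region"] = tuple(d.get("urea_region", (5.5, 6.0)))
        d["manual_edits"] = [tuple(e) for e in d.get("manual_edits", [])]
        return cls(**d)

    def param_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        rng = np.random.default_rng(self.seed)
        seeds = {s: int(rng.integers(2**31 - 1)) for s in STAGES}
        return seeds[stage]

    def validate_paths(self, need_clinical: bool = True) -> None:
        if not Path(self.spectra_dir).is_dir():
            raise FileNotFoundError(f"spectra directory not found: {self.spectra_dir}")
        if need_clinical and not Path(self.clinical_csv).is_file():
            raise FileNotFoundError(f"clinical CSV not found: {self.clinical_csv}")
        for p in (self.peak_library_csv, self.pathway_json):
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"input file not found: {p}")


def load_spectra_dir(spectra_dir) -> list:
    """Read every ``<subject>_<timepoint>.csv`` spectrum in a directory."""
    paths = sorted(Path(spectra_dir).glob("*.csv"))
    paths = [p for p in paths if p.name not in ("clinical.csv", "peak_library.csv")]
    if not paths:
        raise FileNotFoundError(f"no spectrum CSVs in {spectra_dir}")
    spectra = []
    for p in paths:
        stem = p.stem
        subject, _, timepoint = stem.rpartition("_")
        spectra.append(
            Spectrum.from_csv(p, sample_id=stem, subject=subject or stem,
                              timepoint=timepoint)
        )
    return spectra


def assign_bins(bins: BinSet, library: PeakLibrary) -> pd.DataFrame:
    """Map bins to metabolites (and pathway compounds) by peak-center overlap."""
    rows = []
    for k, (lo, hi) in enumerate(bins.edges):
        for m in library.metabolites.values():
            if any(lo <= p.center < hi for p in m.peaks):
                rows.append((f"bin_{k:03d}", m.name, m.compound_id))
    return pd.DataFrame(rows, columns=["bin_id", "metabolite", "compound_id"])


def _library(config: RunConfig) -> PeakLibrary:
    return (PeakLibrary.from_csv(config.peak_library_csv)
            if config.peak_library_csv else default_library())


def _update_manifest(out: Path, config: RunConfig, stage: str, **info) -> None:
    path = out / "manifest.json"
    if path.is_file():
        with open(path) as fh:
            manifest = json.load(fh)
    else:
        manifest = {"stages": [], "seed": config.seed,
                    "param_hash": config.param_hash()}
    seed = config.stage_seed(stage)
    logger.info("stage=%s seed=%d params=%s", stage, seed, config.param_hash())
    manifest["stages"] = [s for s in manifest["stages"] if s["stage"] != stage]
    manifest["stages"].append({"stage": stage, "seed": seed, **info})
    manifest["stages"].sort(key=lambda s: STAGES.index(s["stage"]))
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def _require(out: Path, name: str) -> Path:
    p = out / name
    if not p.is_file():
        raise FileNotFoundError(
            f"missing artifact {name} in {out}; run the producing stage first")
    return p


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_process(config: RunConfig):
    """Alignment, binning, integration and preprocessing -> bin_table/processed."""
    config.validate_paths(need_clinical=False)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    library = _library(config)

    spectra = load_spectra_dir(config.spectra_dir)
    if config.align:
        ref = mean_spectrum(spectra)
        spectra = [align_to_reference(s, ref, max_shift=config.max_shift,
                                      min_segment=config.min_segment)
                   for s in spectra]
        ref = mean_spectrum(spectra)  # recompute once after the first pass
        spectra = [align_to_reference(s, ref, max_shift=config.max_shift,
                                      min_segment=config.min_segment)
                   for s in spectra]
    mean = mean_spectrum(spectra)
    bins = adaptive_bin(mean, min_width=config.min_width,
                        noise_threshold=config.noise_threshold,
                        smooth_window=config.smooth_window)
    if config.manual_edits:
        bins = apply_manual_edits(bins, config.manual_edits)
    bins = exclude_regions(bins, [config.water_region, config.urea_region])
    table = integrate(spectra, bins)
    bins.to_json(out / "bins.json")
    table.to_csv(out / "bin_table.csv")
    assignment = assign_bins(bins, library)
    assignment.to_csv(out / "bin_assignment.csv", index=False)
    _update_manifest(out, config, "spectral_processing",
                     n_spectra=len(spectra), n_bins=len(bins))

    matrix = preprocess(table)
    matrix.to_csv(out / "processed.csv", sidecar=out / "processed_params.json")
    pd.DataFrame(matrix.normalized, index=matrix.sample_ids,
                 columns=matrix.normalized_bin_ids).to_csv(out / "normalized.csv")
    _update_manifest(out, config, "preprocessing",
                     n_retained=len(matrix.bin_ids),
                     n_excluded=len(matrix.excluded_bins))
    return {"bins": bins, "table": table, "assignment": assignment,
            "matrix": matrix}


def _load_matrix(out: Path) -> ProcessedMatrix:
    return load_processed(_require(out, "processed.csv"),
                          _require(out, "processed_params.json"),
                          _require(out, "normalized.csv"))


def stage_univariate(config: RunConfig, matrix: ProcessedMatrix | None = None):
    out = Path(config.out_dir)
    matrix = matrix or _load_matrix(out)
    results, significant = test_all_bins(matrix, alpha=config.alpha,
                                         alpha_normality=config.alpha_normality)
    uni = pd.DataFrame(
        [(r.bin_id, r.test, r.statistic, r.p, r.direction) for r in results],
        columns=["bin", "test", "statistic", "p", "direction"],
    )
    uni.to_csv(out / "univariate.csv", index=False)
    _update_manifest(out, config, "univariate_stats",
                     n_significant=len(significant))
    return {"univariate": uni, "significant_bins": significant}


def stage_viavc(config: RunConfig, matrix: ProcessedMatrix | None = None):
    out = Path(config.out_dir)
    matrix = matrix or _load_matrix(out)
    selector = VIAVCSelector(
        n_rows=config.viavc_rows, inclusion_prob=config.inclusion_prob,
        folds=config.folds, max_k=config.max_k, alpha=config.alpha,
        random_state=config.stage_seed("viavc_selection"),
    ).fit(matrix.data, matrix.labels, bin_ids=matrix.bin_ids)
    result = selector.result()
    result.to_json(out / "viavc.json")
    ranked = pd.DataFrame(
        {
            "bin": [matrix.bin_ids[i] for i in result.ranking],
            "importance": result.importances[result.ranking],
            "category": result.categories[result.ranking],
            "rank": np.arange(1, len(result.ranking) + 1),
        }
    )
    ranked.to_csv(out / "viavc_ranking.csv", index=False)
    best_ids = [matrix.bin_ids[i] for i in result.best_subset]
    _update_manifest(out, config, "viavc_selection",
                     best_subset=best_ids, best_auc=result.best_auc)
    return {"viavc": result, "best_subset_ids": best_ids}


def _load_union(out: Path, config: RunConfig, matrix: ProcessedMatrix):
    uni = pd.read_csv(_require(out, "univariate.csv"))
    significant = uni.loc[uni["p"].notna() & (uni["p"] < config.alpha), "bin"].tolist()
    viavc_result = VIAVCResult.from_json(_require(out, "viavc.json"))
    best_ids = [matrix.bin_ids[i] for i in viavc_result.best_subset]
    union = sorted(set(significant) | set(best_ids))
    return union, viavc_result, best_ids


def stage_multivariate(config: RunConfig, matrix: ProcessedMatrix | None = None):
    out = Path(config.out_dir)
    matrix = matrix or _load_matrix(out)
    union, _, _ = _load_union(out, config, matrix)
    union_idx = [matrix.bin_ids.index(b) for b in union]
    Xu = matrix.data[:, union_idx] if union_idx else matrix.data
    y = matrix.labels
    seed = config.stage_seed("multivariate_models")

    scores, loadings, evr = pca(Xu, n_components=min(2, Xu.shape[0] - 1))
    model = OPLSDA(n_orthogonal=1).fit(Xu, y)
    q2 = double_cv_q2(Xu, y, outer_folds=config.folds, inner_folds=config.folds,
                      seed=seed, max_orthogonal=config.max_orthogonal)
    perm_r2y = permutation_test(Xu, y, statistic="R2Y",
                                n_perm=config.n_perm, seed=seed)
    perm_q2 = permutation_test(
        Xu, y, statistic="Q2", n_perm=max(1, config.n_perm // 10), seed=seed,
        outer_folds=config.folds, inner_folds=config.folds,
        max_orthogonal=config.max_orthogonal,
    )
    order = hierarchical_heatmap_order(Xu)
    summary = {
        "R2Y": model.R2Y_, "Q2": q2, "p_R2Y": perm_r2y.p, "p_Q2": perm_q2.p,
        "n_orthogonal": model.n_orthogonal_, "n_union_bins": len(union),
        "pca_explained_variance": list(map(float, evr)), "seed": seed,
    }
    with open(out / "model_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    pd.DataFrame(
        {
            "sample": matrix.sample_ids,
            "timepoint": list(y),
            "pc1": scores[:, 0],
            "pc2": scores[:, 1] if scores.shape[1] > 1 else np.nan,
            "oplsda_predictive": model.scores_,
            "oplsda_orthogonal": model.orthogonal_scores_[:, 0]
            if model.n_orthogonal_ else np.zeros(len(y)),
            "heatmap_row_order": np.argsort(order.row_order),
        }
    ).to_csv(out / "scores.csv", index=False)
    _update_manifest(out, config, "multivariate_models",
                     **{k: summary[k] for k in ("R2Y", "Q2", "p_R2Y", "p_Q2")})
    return {"model_summary": summary, "cluster_order": order, "model": model}


def stage_roc(config: RunConfig, matrix: ProcessedMatrix | None = None):
    out = Path(config.out_dir)
    matrix = matrix or _load_matrix(out)
    viavc_result = VIAVCResult.from_json(_require(out, "viavc.json"))
    y = matrix.labels
    ym, _ = _encode_labels(y)
    seed = config.stage_seed("biomarker_roc")
    splits = make_splits(y, config.folds, np.random.default_rng(seed))
    roc_scores = cv_plsda_scores(matrix.data[:, viavc_result.best_subset], ym, splits)
    roc = roc_curve(roc_scores, y)
    roc.ci = bootstrap_ci(roc_scores, y, n_boot=config.n_boot, seed=seed)
    roc.n_bootstrap = config.n_boot
    roc.seed = seed
    roc.accuracies = panel_accuracy(matrix.data, y, viavc_result.best_subset,
                                    folds=config.folds, seed=seed)
    roc.to_json(out / "roc.json")
    _update_manifest(out, config, "biomarker_roc", auc=roc.auc, ci=list(roc.ci))
    return {"roc": roc}


def stage_correlation(config: RunConfig, matrix: ProcessedMatrix | None = None):
    out = Path(config.out_dir)
    if not Path(config.clinical_csv).is_file():
        raise FileNotFoundError(f"clinical CSV not found: {config.clinical_csv}")
    matrix = matrix or _load_matrix(out)
    clinical = clin.load_clinical(config.clinical_csv)
    viavc_result = VIAVCResult.from_json(_require(out, "viavc.json"))

    tps = sorted(set(matrix.timepoints))
    norm = pd.DataFrame(matrix.normalized, index=matrix.sample_ids,
                        columns=matrix.normalized_bin_ids)
    subj = pd.Series(matrix.subjects, index=matrix.sample_ids)
    tp = pd.Series(matrix.timepoints, index=matrix.sample_ids)
    initial = norm[(tp == tps[0]).values].set_index(subj[(tp == tps[0]).values])
    post = norm[(tp == tps[1]).values].set_index(subj[(tp == tps[1]).values])
    delta = clin.metabolite_delta(initial, post.loc[initial.index])
    pct = clinical.set_index("subject").apply(
        lambda r: clin.scim_pct_diff(r["scim_pre"], r["scim_post"]), axis=1)
    pct = pct.loc[[s for s in initial.index if s in pct.index]]
    head = [matrix.bin_ids[i]
            for i in viavc_result.f_ranked_head(config.top_f_ranked)]
    head = [b for b in head if b in norm.columns]
    corr = clin.correlate_biomarkers(initial.loc[pct.index], delta.loc[pct.index],
                                     pct, head, alpha=config.alpha)
    corr_df = pd.DataFrame(
        [(c.bin_id, c.predictor, c.r, c.p, c.threshold, c.significant)
         for c in corr],
        columns=["bin", "predictor", "r", "p", "threshold", "significant"],
    )
    corr_df.to_csv(out / "correlations.csv", index=False)
    _update_manifest(out, config, "clinical_correlation", n_tested=len(head),
                     n_significant=int(corr_df["significant"].sum()))
    return {"correlations": corr_df}


def stage_pathway(config: RunConfig, matrix: ProcessedMatrix | None = None):
    out = Path(config.out_dir)
    matrix = matrix or _load_matrix(out)
    assignment = pd.read_csv(_require(out, "bin_assignment.csv"))
    union, _, _ = _load_union(out, config, matrix)
    pathway_library = (pw.PathwayLibrary.from_json(config.pathway_json)
                       if config.pathway_json else pw.default_pathway_library())
    sig_compounds = assignment.loc[
        assignment["bin_id"].isin(union), "compound_id"
    ].drop_duplicates().tolist()
    screen = pw.pathway_screen(sig_compounds, pathway_library, alpha=config.alpha)
    path_df = pd.DataFrame(
        [(r.pathway_id, r.name, r.hits, r.size, r.p, r.impact,
          ";".join(r.matched)) for r in screen],
        columns=["pathway", "name", "hits", "size", "p", "impact", "matched"],
    )
    path_df.to_csv(out / "pathways.csv", index=False)
    _update_manifest(out, config, "pathway_analysis",
                     top_pathway=screen[0].pathway_id if screen else None)
    return {"pathways": path_df, "screen": screen}


def run_pipeline(config: RunConfig):
    """Execute all stages in order; returns a dict of in-memory artifacts."""
    config.validate_paths()
    artifacts: dict = {}
    current = "spectral_processing"
    try:
        artifacts.update(stage_process(config))
        matrix = artifacts["matrix"]
        for current, fn in (
            ("univariate_stats", stage_univariate),
            ("viavc_selection", stage_viavc),
            ("multivariate_models", stage_multivariate),
            ("biomarker_roc", stage_roc),
            ("clinical_correlation", stage_correlation),
            ("pathway_analysis", stage_pathway),
        ):
            artifacts.update(fn(config, matrix))
    except FileNotFoundError:
        raise
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {current!r}: {err}") from err
    with open(Path(config.out_dir) / "manifest.json") as fh:
        artifacts["manifest"] = json.load(fh)
    return artifacts


def report(out_dir) -> str:
    """Plain-text summary of a finished run directory."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.is_file():
        raise FileNotFoundError(f"no manifest at {manifest_path}; run the pipeline first")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    stages = {s["stage"]: s for s in manifest["stages"]}
    lines = ["uromet run summary", "==================",
             f"seed: {manifest['seed']}  params: {manifest['param_hash']}"]
    if "univariate_stats" in stages:
        lines.append(
            f"univariate significant bins: {stages['univariate_stats']['n_significant']}")
    if "viavc_selection" in stages:
        s = stages["viavc_selection"]
        lines.append(f"VIAVC best subset: {s['best_subset']} (AUC {s['best_auc']:.3f})")
    if "multivariate_models" in stages:
        s = stages["multivariate_models"]
        lines.append(
            f"OPLS-DA: R2Y {s['R2Y']:.3f} (p {s['p_R2Y']:.4f}), "
            f"Q2 {s['Q2']:.3f} (p {s['p_Q2']:.4f})")
    if "biomarker_roc" in stages:
        s = stages["biomarker_roc"]
        lines.append(f"ROC AUC {s['auc']:.3f} (95% CI {s['ci'][0]:.3f}-{s['ci'][1]:.3f})")
    if "clinical_correlation" in stages:
        s = stages["clinical_correlation"]
        lines.append(
            f"correlations: {s['n_significant']} significant of {s['n_tested']} tested x2")
    if "pathway_analysis" in stages:
        lines.append(f"top pathway: {stages['pathway_analysis']['top_pathway']}")
    return "\n".join(lines)
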