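"""End-to-end genomic-prediction experiments.

Orchestrates the full study design: training-only GWAS, top-N variant
preselection, reliable-SNP voting, trait-specific GRM construction, GBLUP
variants (with/without fixed principal components and fixed-effect SNPs)
and the two validation designs -- hold-out of the breeding-program
parents, and repeated 5-fold cross-validation. Validation phenotypes are
never visible to GWAS, preselection or REML: marker discovery is re-run
inside every training split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix
from .gwas import (
    GWASResult,
    blink_scan,
    farmcpu_scan,
    glm_scan,
    mlmm_scan,
    reliable_snps,
)
from .ldtools import PruneSpec, prune
from .mixedmodel import REMLFit, build_design, heritability, reml_fit
from .relmat import GRM, bend, grm_pca, vanraden_grm

__all__ = [
    "Dataset",
    "MarkerSet",
    "ScenarioConfig",
    "predictive_ability",
    "prediction_bias",
    "preselect_top_n",
    "compute_pc_scores",
    "fit_and_predict",
    "parental_validation",
    "kfold_cv",
    "run_scenario",
]

VARIANTS = ("base", "fixed_pcs", "fixed_snps", "both")


@dataclass
class Dataset:
    """Complete genotypes plus phenotypes for a gene-pool collection."""

    geno: GenotypeMatrix  # QC'd and imputed: no missing dosages
    pheno: pd.Series  # indexed by individual id
    covariates: pd.DataFrame | None = None  # e.g. assessment age
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.geno.dosages).any():
            raise ValueError("Dataset requires complete dosages; impute first")
        unknown = set(self.pheno.index) - set(self.geno.ids)
        if unknown:
            raise ValueError(f"phenotyped individuals missing genotypes: {sorted(unknown)[:5]}")

    def phenotyped_ids(self) -> list:
        return list(self.pheno.dropna().index)


@dataclass(frozen=True)
class MarkerSet:
    """One marker panel to evaluate: full, LD-pruned, or GWAS top-N."""

    kind: str  # "full" | "prune" | "top"
    prune_spec: PruneSpec | None = None
    method: str | None = None  # GWAS method for kind="top"
    n: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("full", "prune", "top"):
            raise ValueError("kind must be full, prune or top")
        if self.kind == "prune" and self.prune_spec is None:
            raise ValueError("prune marker set needs a PruneSpec")
        if self.kind == "top" and (self.method is None or not self.n or self.n <= 0):
            raise ValueError("top marker set needs a GWAS method and positive n")


@dataclass
class ScenarioConfig:
    """Factorial layout of one prediction experiment."""

    marker_sets: dict = field(default_factory=lambda: {"full": MarkerSet("full")})
    variants: tuple = VARIANTS
    n_pcs: int = 6
    validation: str = "parental"  # or "kfold"
    parental_ids: tuple | None = None
    k: int = 5
    repeats: int = 5
    seed: int = 0
    pca_prune: PruneSpec | None = PruneSpec()
    gwas_alpha: float = 0.05
    reliable_methods: tuple = ("glm", "farmcpu")
    min_methods: int = 2

    def __post_init__(self) -> None:
        bad = set(self.variants) - set(VARIANTS)
        if bad:
            raise ValueError(f"unknown model variants: {sorted(bad)}")


def predictive_ability(y_obs, y_pred) -> float:
    """Pearson correlation between observed and predicted phenotypes."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if y_obs.std() == 0 or y_pred.std() == 0:
        warnings.warn("predictive ability undefined: zero variance")
        return float("nan")
    return float(np.corrcoef(y_obs, y_pred)[0, 1])


def prediction_bias(y_obs, y_pred) -> float:
    """OLS slope of observed phenotype on prediction; 1 means unbiased."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_pred.std() == 0:
        raise ValueError("constant predictions: bias slope undefined")
    xc = y_pred - y_pred.mean()
    return float((xc @ (y_obs - y_obs.mean())) / (xc @ xc))


def preselect_top_n(result: GWASResult, n: int) -> list:
    """The n most significant markers; ties broken by (p, chrom, pos)."""
    if n <= 0:
        raise ValueError("n must be positive")
    t = result.table.dropna(subset=["p"])
    if n > len(t):
        raise ValueError(f"n={n} exceeds {len(t)} tested markers")
    t = t.sort_values(["p", "chrom", "pos"], kind="mergesort")
    return list(t["marker"].head(n))


def compute_pc_scores(data: Dataset, config: ScenarioConfig) -> pd.DataFrame:
    """Structure covariates: top PCs of a GRM built on a pruned panel.

    Computed once on all individuals -- population structure is a
    property of the whole collection, and genotypes carry no phenotype
    information, so this does not leak validation phenotypes.
    """
    geno = data.geno
    if config.pca_prune is not None:
        kept = prune(geno, config.pca_prune)
        geno = geno.subset(markers=kept)
    grm = vanraden_grm(geno)
    scores = grm_pca(grm, config.n_pcs)
    return scores.to_frame()


_SCANNERS = {
    "glm": lambda y, g, cov, grm, alpha: glm_scan(y, g, cov, alpha),
    "mlmm": lambda y, g, cov, grm, alpha: mlmm_scan(y, g, grm, cov, alpha=alpha),
    "farmcpu": lambda y, g, cov, grm, alpha: farmcpu_scan(y, g, cov, alpha=alpha),
    "blink": lambda y, g, cov, grm, alpha: blink_scan(y, g, cov, alpha=alpha),
}


def _train_gwas(data, train_ids, method, pc_scores, config, grm=None):
    """Run one GWAS on the training individuals only."""
    if method not in _SCANNERS:
        raise ValueError(f"unknown GWAS method {method!r}; use {sorted(_SCANNERS)}")
    y = data.pheno.loc[train_ids]
    geno_tr = data.geno.subset(individuals=train_ids)
    cov = pc_scores.loc[train_ids].to_numpy() if pc_scores is not None else None
    grm_tr = None
    if method == "mlmm":
        grm_tr = bend(vanraden_grm(geno_tr))
    return _SCANNERS[method](y, geno_tr, cov, grm_tr, config.gwas_alpha)


def fit_and_predict(
    data: Dataset,
    train_ids,
    val_ids,
    marker_ids=None,
    use_pcs: bool = False,
    fixed_snp_ids=(),
    pc_scores: pd.DataFrame | None = None,
    n_pcs: int = 6,
) -> tuple[pd.Series, REMLFit]:
    """Fit GBLUP on the training records and predict the validation set.

    The GRM covers training and validation individuals jointly (their
    genotypes are known; only validation phenotypes are held out); fixed
    SNPs are excluded from the GRM and their BLUE contributions are added
    to the validation GEBVs. Fixed-PC contributions are treated as
    nuisance structure and are not added to predicted merit.
    """
    train_ids = list(train_ids)
    val_ids = list(val_ids)
    fixed_snp_ids = list(fixed_snp_ids)
    panel = list(marker_ids) if marker_ids is not None else list(data.geno.marker_ids)
    grm_panel = [m for m in panel if m not in set(fixed_snp_ids)]
    everyone = train_ids + [v for v in val_ids if v not in set(train_ids)]

    geno_grm = data.geno.subset(individuals=everyone, markers=grm_panel)
    grm = bend(vanraden_grm(geno_grm))

    snp_df = None
    if fixed_snp_ids:
        geno_snp = data.geno.subset(individuals=everyone, markers=fixed_snp_ids)
        snp_df = pd.DataFrame(
            geno_snp.dosages, index=everyone, columns=fixed_snp_ids
        )
    pcs = None
    if use_pcs:
        if pc_scores is None:
            raise ValueError("use_pcs=True requires pc_scores")
        pcs = pc_scores.iloc[:, :n_pcs]

    X = build_design(
        train_ids,
        covariates=None if data.covariates is None else data.covariates,
        pc_scores=pcs,
        snp_dosages=None if snp_df is None else snp_df,
    )
    fit = reml_fit(data.pheno.loc[train_ids], X, grm, record_ids=train_ids)

    pred = fit.gebv.loc[val_ids].copy()
    if fixed_snp_ids:
        blues = fit.blues[[f"snp:{s}" for s in fixed_snp_ids]].to_numpy()
        pred += snp_df.loc[val_ids].to_numpy() @ blues
    return pred.rename("predicted"), fit


def _resolve_marker_sets(data, config, train_ids, pc_scores, cache):
    """Materialise each configured marker panel for one training split."""
    panels = {}
    for name, ms in config.marker_sets.items():
        if ms.kind == "full":
            panels[name] = list(data.geno.marker_ids)
        elif ms.kind == "prune":
            key = ("prune", ms.prune_spec)
            if key not in cache:  # genotype-only: split-independent
                cache[key] = prune(data.geno, ms.prune_spec)
            panels[name] = cache[key]
        else:
            scan = _train_gwas(data, train_ids, ms.method, pc_scores, config)
            panels[name] = preselect_top_n(scan, min(ms.n, len(scan.table.dropna(subset=["p"]))))
    return panels


def _evaluate_split(data, config, train_ids, val_ids, pc_scores, cache, tag):
    """All marker-set x model-variant cells for one train/val split."""
    need_reliable = any(v in ("fixed_snps", "both") for v in config.variants)
    reliable_ids: list = []
    if need_reliable:
        scans = [
            _train_gwas(data, train_ids, m, pc_scores, config)
            for m in config.reliable_methods
        ]
        reliable_ids = reliable_snps(scans, config.min_methods).marker_ids
    panels = _resolve_marker_sets(data, config, train_ids, pc_scores, cache)

    rows = []
    y_val = data.pheno.loc[val_ids].to_numpy(dtype=float)
    for set_name, panel in panels.items():
        for variant in config.variants:
            use_pcs = variant in ("fixed_pcs", "both")
            snps = reliable_ids if variant in ("fixed_snps", "both") else []
            pred, fit = fit_and_predict(
                data,
                train_ids,
                val_ids,
                marker_ids=panel,
                use_pcs=use_pcs,
                fixed_snp_ids=snps,
                pc_scores=pc_scores,
                n_pcs=config.n_pcs,
            )
            rows.append(
                dict(
                    marker_set=set_name,
                    variant=variant,
                    fold=tag[0],
                    repeat=tag[1],
                    pa=predictive_ability(y_val, pred.to_numpy()),
                    bias=prediction_bias(y_val, pred.to_numpy()),
                    h2=heritability(fit),
                    aic=fit.aic,
                    n_validation=len(val_ids),
                    n_markers=len(panel),
                    n_fixed_snps=len(snps),
                )
            )
    return rows


def parental_validation(data: Dataset, config: ScenarioConfig) -> pd.DataFrame:
    """Hold out the breeding-program parents as the validation set."""
    if not config.parental_ids:
        raise ValueError("parental validation requires parental_ids")
    parents = [p for p in config.parental_ids if p in data.pheno.dropna().index]
    if len(parents) < 3:
        raise ValueError("need at least 3 phenotyped validation individuals")
    train = [i for i in data.phenotyped_ids() if i not in set(config.parental_ids)]
    pc_scores = compute_pc_scores(data, config)
    rows = _evaluate_split(data, config, train, parents, pc_scores, {}, (0, 0))
    return pd.DataFrame(rows)


def kfold_cv(data: Dataset, config: ScenarioConfig) -> pd.DataFrame:
    """Repeated k-fold cross-validation over the phenotyped collection.

    Every repeat draws a fresh random partition (fold sizes differing by
    at most one); GWAS-based preselection and reliable-SNP voting are
    re-run inside each fold's training split, so marker discovery never
    sees the fold's validation phenotypes.
    """
    ids = np.array(data.phenotyped_ids())
    if len(ids) < config.k:
        raise ValueError("fewer phenotyped individuals than folds")
    if config.k < 2:
        raise ValueError("k must be >= 2")
    pc_scores = compute_pc_scores(data, config)
    cache: dict = {}
    rows = []
    for rep in range(config.repeats):
        rng = np.random.default_rng([config.seed, rep])
        perm = rng.permutation(len(ids))
        folds = np.array_split(perm, config.k)
        for fold_no, val_pos in enumerate(folds):
            val = list(ids[val_pos])
            train = [i for i in ids if i not in set(val)]
            rows.extend(
                _evaluate_split(
                    data, config, train, val, pc_scores, cache, (fold_no, rep)
                )
            )
    return pd.DataFrame(rows)


@dataclass
class ScenarioReport:
    """Long-format results plus the optimal preselection density per method."""

    table: pd.DataFrame
    optimal_density: dict


def run_scenario(data: Dataset, config: ScenarioConfig) -> ScenarioReport:
    """Full factorial: marker sets x model variants x validation design."""
    if config.validation == "parental":
        table = parental_validation(data, config)
    elif config.validation == "kfold":
        table = kfold_cv(data, config)
    else:
        raise ValueError("validation must be 'parental' or 'kfold'")

    optimal: dict = {}
    top_sets = {
        name: ms for name, ms in config.marker_sets.items() if ms.kind == "top"
    }
    by_method: dict = {}
    for name, ms in top_sets.items():
        by_method.setdefault(ms.method, []).append((name, ms.n))
    for method, sets in by_method.items():
        means = []
        for name, n in sets:
            sub = table[(table.marker_set == name) & (table.variant == "base")]
            if len(sub):
                means.append((-(sub.pa.mean()), n, name))
        if means:
            means.sort()  # best mean PA first, ties to the smaller N
            optimal[method] = dict(marker_set=means[0][2], n=means[0][1])
    return ScenarioReport(table=table, optimal_density=optimal)
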