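"""Synthetic structured genotypes and quantitative traits.

Emulates the statistical structure of a perennial-crop gene pool built
from two admixture-free subpopulations: divergent subpopulation allele
frequencies follow the Balding-Nichols model around a shared ancestral
frequency, and within-subpopulation linkage disequilibrium arises from a
founder-mosaic copying process whose per-bp template switch rate sets the
r2 decay length. Traits are additive (optionally with one major locus and
a subpopulation mean shift that confounds structure with the trait), with
the residual scaled so the realized narrow-sense heritability matches the
target. Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, read_vcf

__all__ = [
    "SimConfig",
    "SimResult",
    "TraitTruth",
    "simulate_structured_genotypes",
    "simulate_phenotype",
    "discretize_liability",
    "write_fixture",
    "hudson_fst",
]


@dataclass
class SimConfig:
    """Parameters of the structured-population genotype generator.

    Defaults mirror the gene pool the pipeline is designed around: two
    subpopulations of 192 and 33 accessions with Fst ~ 0.2 divergence,
    few founder haplotypes (strong short-range LD) and a switch rate that
    puts the r2 = 0.2 decay distance in the low-kb range.
    """

    n_subpop1: int = 192
    n_subpop2: int = 33
    n_snps: int = 3000
    n_chrom: int = 5
    chrom_length_bp: int = 2_000_000
    fst: float = 0.2
    n_founder_haps: int = 5
    switch_rate: float = 2e-5
    maf_floor: float = 0.05
    dp_mean: float = 15.0
    low_depth_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if not (0 < self.switch_rate < 1):
            raise ValueError("switch_rate must be in (0, 1)")
        if self.n_founder_haps < 2:
            raise ValueError("need at least 2 founder haplotypes")
        for name in ("n_subpop1", "n_subpop2", "n_snps", "n_chrom", "chrom_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in [0, 0.5)")


@dataclass
class SimResult:
    """Genotypes plus the generative ground truth needed by tests."""

    geno: GenotypeMatrix
    labels: np.ndarray  # 0 = subpop1, 1 = subpop2
    ancestral_freq: np.ndarray
    subpop_freq: np.ndarray  # shape (2, m): the Balding-Nichols draws


@dataclass
class TraitTruth:
    """Ground truth of a simulated trait."""

    qtl_ids: list
    qtl_effects: np.ndarray
    true_breeding_values: pd.Series
    target_h2: float
    realized_h2: float
    subpop_shift: float
    major_qtl_variance_fraction: float
    major_qtl_id: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            dict(
                qtl_ids=list(map(str, self.qtl_ids)),
                qtl_effects=list(map(float, self.qtl_effects)),
                true_breeding_values={
                    str(k): float(v) for k, v in self.true_breeding_values.items()
                },
                target_h2=self.target_h2,
                realized_h2=self.realized_h2,
                subpop_shift=self.subpop_shift,
                major_qtl_variance_fraction=self.major_qtl_variance_fraction,
                major_qtl_id=self.major_qtl_id,
            ),
            indent=2,
        )


def simulate_structured_genotypes(config: SimConfig) -> SimResult:
    """Simulate diploid dosages for a two-subpopulation gene pool.

    Ancestral frequencies are Uniform(maf_floor, 1 - maf_floor); each
    subpopulation draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F)
    (the shared ancestral p when F = 0). Within a subpopulation, the
    founder pool carries the alt allele on round(K * p_s) of its K
    haplotypes, and every sampled haplotype is a mosaic of founder
    templates with switches at ``switch_rate`` per bp, so pairwise r2
    decays with physical distance.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    K = config.n_founder_haps

    # Marker map: markers spread over chromosomes, unique sorted positions.
    per_chrom = np.full(config.n_chrom, m // config.n_chrom)
    per_chrom[: m % config.n_chrom] += 1
    chroms, positions = [], []
    for c, mc in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(config.chrom_length_bp, size=mc, replace=False)) + 1
        chroms.append(np.full(mc, f"chr{c}", dtype=object))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)

    p_anc = rng.uniform(config.maf_floor, 1 - config.maf_floor, size=m)
    if config.fst == 0:
        subpop_freq = np.vstack([p_anc, p_anc])
    else:
        ratio = (1 - config.fst) / config.fst
        subpop_freq = rng.beta(p_anc * ratio, (1 - p_anc) * ratio, size=(2, m))

    n_by_pop = (config.n_subpop1, config.n_subpop2)
    # one ancestral founder ordering per locus, shared by both subpopulations,
    # so their founder pools carry consistent (ancestral) LD
    founder_order = np.argsort(rng.random((K, m)), axis=0)
    dosage_blocks = []
    for s in (0, 1):
        founders = _founder_pool(subpop_freq[s], founder_order)
        haps = _mosaic_haplotypes(
            founders, 2 * n_by_pop[s], chrom, pos, config.switch_rate, rng
        )
        dosage_blocks.append(haps[0::2] + haps[1::2])
    dosages = np.vstack(dosage_blocks).astype(float)

    depth = rng.poisson(config.dp_mean, size=dosages.shape).astype(float)
    if config.low_depth_frac > 0:
        low = rng.random(dosages.shape) < config.low_depth_frac
        depth[low] = rng.integers(0, 5, size=int(low.sum()))

    ids = np.array(
        [f"P1_{i:04d}" for i in range(config.n_subpop1)]
        + [f"P2_{i:04d}" for i in range(config.n_subpop2)],
        dtype=object,
    )
    labels = np.r_[
        np.zeros(config.n_subpop1, dtype=int), np.ones(config.n_subpop2, dtype=int)
    ]
    markers = pd.DataFrame(
        dict(
            chrom=chrom,
            pos=pos,
            ref="A",
            alt="G",
            id=[f"{c}_{p}" for c, p in zip(chrom, pos)],
        )
    )
    geno = GenotypeMatrix(ids=ids, markers=markers, dosages=dosages, depth=depth)
    return SimResult(
        geno=geno, labels=labels, ancestral_freq=p_anc, subpop_freq=subpop_freq
    )


def _founder_pool(freqs: np.ndarray, founder_order: np.ndarray) -> np.ndarray:
    """Founder haplotypes whose per-locus alt counts are round(K * p).

    Rounded counts (rather than i.i.d. Bernoulli founders) keep the
    realized subpopulation frequency at the Balding-Nichols draw up to
    O(1/K) granularity, so divergence is governed by Fst alone and not by
    extra founder drift. The alt allele goes to the first round(K*p)
    founders of the supplied per-locus ordering.
    """
    K = founder_order.shape[0]
    counts = np.round(K * freqs).astype(int)
    return (founder_order < counts[None, :]).astype(np.int8)


def _mosaic_haplotypes(founders, n_haps, chrom, pos, switch_rate, rng):
    """Sample haplotypes as founder mosaics with per-bp template switches."""
    K, m = founders.shape
    gaps = np.abs(np.diff(pos)).astype(float)
    q = 1.0 - np.exp(-switch_rate * gaps)
    switch = np.empty((n_haps, m), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((n_haps, m - 1)) < q[None, :]
    # new chromosome => always redraw the template
    new_chrom = np.r_[True, np.asarray(chrom[1:]) != np.asarray(chrom[:-1])]
    switch |= new_chrom[None, :]
    templates = rng.integers(0, K, size=(n_haps, m))
    cols = np.arange(m)
    last_event = np.maximum.accumulate(np.where(switch, cols[None, :], 0), axis=1)
    template = templates[np.arange(n_haps)[:, None], last_event]
    return founders[template, cols[None, :]]


def simulate_phenotype(
    geno: GenotypeMatrix,
    labels: np.ndarray,
    n_qtl: int,
    target_h2: float,
    major_qtl_variance_fraction: float = 0.0,
    subpop_shift: float = 0.0,
    seed: int = 0,
) -> tuple[pd.Series, TraitTruth]:
    """Simulate an additive trait on existing genotypes.

    y_i = sum_k x_ik b_k + shift * 1[i in subpop 2] + e_i, with the
    residual rescaled so the realized (sample) heritability before the
    shift equals ``target_h2`` exactly. When
    ``major_qtl_variance_fraction`` > 0, one QTL's effect is rescaled so
    its term contributes exactly that fraction of var(true BV).
    """
    if n_qtl <= 0:
        raise ValueError("n_qtl must be positive for a heritable trait")
    if n_qtl > geno.n_markers:
        raise ValueError("n_qtl exceeds the number of markers")
    if not (0 < target_h2 < 1):
        raise ValueError("target_h2 must be in (0, 1)")
    if np.isnan(geno.dosages).any():
        raise ValueError("genotypes must be complete (impute first)")

    rng = np.random.default_rng(seed)
    qtl_idx = np.sort(rng.choice(geno.n_markers, size=n_qtl, replace=False))
    effects = rng.normal(0.0, 1.0, size=n_qtl)
    X = geno.dosages[:, qtl_idx]

    major_id = None
    f = major_qtl_variance_fraction
    if f > 0:
        if not f < 1:
            raise ValueError("major_qtl_variance_fraction must be in [0, 1)")
        # most variable selected QTL becomes the major locus
        j = int(np.argmax(X.var(axis=0)))
        x1 = X[:, j]
        rest = np.delete(np.arange(n_qtl), j)
        g_rest = X[:, rest] @ effects[rest]
        v1 = x1.var(ddof=1)
        vr = g_rest.var(ddof=1)
        c = np.cov(x1, g_rest, ddof=1)[0, 1]
        # solve (1-f) v1 b^2 - 2 f c b - f vr = 0 for the positive root
        b1 = (f * c + np.sqrt(f * f * c * c + f * (1 - f) * v1 * vr)) / ((1 - f) * v1)
        effects[j] = b1
        major_id = geno.markers["id"].iloc[qtl_idx[j]]

    g = X @ effects
    var_g = g.var(ddof=1)
    if var_g <= 0:
        raise ValueError("genetic variance is zero; QTLs are monomorphic")
    # normalise the genetic scale: var(true BV) = 1, so subpop_shift and
    # residuals are expressed in genetic-standard-deviation units
    effects /= np.sqrt(var_g)
    g = X @ effects
    var_g = g.var(ddof=1)
    sigma_e2 = var_g * (1 - target_h2) / target_h2
    e = rng.normal(size=geno.n_individuals)
    e = e - e.mean()
    # orthogonalise against g so the realized variance ratio is exact
    gc = g - g.mean()
    e -= gc * (e @ gc) / (gc @ gc)
    e *= np.sqrt(sigma_e2) / e.std(ddof=1)

    y = g + subpop_shift * (np.asarray(labels) == 1) + e
    realized_h2 = var_g / (var_g + e.var(ddof=1))
    pheno = pd.Series(y, index=pd.Index(geno.ids, name="id"), name="trait")
    truth = TraitTruth(
        qtl_ids=list(geno.markers["id"].to_numpy()[qtl_idx]),
        qtl_effects=effects,
        true_breeding_values=pd.Series(g, index=pheno.index, name="true_bv"),
        target_h2=target_h2,
        realized_h2=float(realized_h2),
        subpop_shift=subpop_shift,
        major_qtl_variance_fraction=f,
        major_qtl_id=major_id,
    )
    return pheno, truth


def discretize_liability(values, n_classes: int = 6) -> np.ndarray:
    """Map a continuous liability onto ordinal classes 0..n_classes-1.

    Thresholds are the equal-probability quantiles of the input, so
    classes are (near-)equally filled and the mapping is monotone.
    A constant input collapses into a single class, with a warning.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if np.ptp(values) == 0:
        warnings.warn("constant liability: all observations fall in one class")
        return np.zeros(values.shape, dtype=int)
    thresholds = np.quantile(values, np.arange(1, n_classes) / n_classes)
    return np.searchsorted(thresholds, values, side="left").astype(int)


def hudson_fst(dosages: np.ndarray, labels: np.ndarray) -> float:
    """Hudson-type Fst averaged over markers (ratio of averages).

    Uses allele frequencies of the two groups with the standard
    finite-sample correction on the numerator; dosage input is assumed
    complete and diploid.
    """
    labels = np.asarray(labels)
    d1 = dosages[labels == np.unique(labels)[0]]
    d2 = dosages[labels == np.unique(labels)[1]]
    n1, n2 = 2 * d1.shape[0], 2 * d2.shape[0]
    p1 = d1.mean(axis=0) / 2
    p2 = d2.mean(axis=0) / 2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].mean() / den[keep].mean())


def write_fixture(
    geno: GenotypeMatrix,
    pheno: pd.Series,
    truth: TraitTruth | None,
    labels: np.ndarray | None,
    out_dir,
    overwrite: bool = False,
) -> dict:
    """Write a simulated dataset as VCF + CSV + JSON ground truth.

    Produces ``genotypes.vcf`` (GT:DP), ``phenotypes.csv``,
    ``subpops.csv`` and ``truth.json``; the VCF round-trips through
    :func:`mangogp.geno_io.read_vcf` losslessly for dosages.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    paths = {"vcf": out_dir / "genotypes.vcf"}
    _write_vcf(geno, paths["vcf"])

    paths["pheno"] = out_dir / "phenotypes.csv"
    pheno.rename_axis("id").to_frame("value").to_csv(paths["pheno"])

    if labels is not None:
        paths["labels"] = out_dir / "subpops.csv"
        pd.DataFrame({"id": geno.ids, "subpop": np.asarray(labels)}).to_csv(
            paths["labels"], index=False
        )
    if truth is not None:
        paths["truth"] = out_dir / "truth.json"
        paths["truth"].write_text(truth.to_json())
    return paths


def _write_vcf(geno: GenotypeMatrix, path) -> None:
    chrom_lengths = geno.markers.groupby("chrom", sort=False)["pos"].max()
    lines = ["##fileformat=VCFv4.2", "##source=mangogp.simdata"]
    for c, ln in chrom_lengths.items():
        lines.append(f"##contig=<ID={c},length={int(ln)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(map(str, geno.ids))
    )
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    depth = geno.depth
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for j, row in enumerate(geno.markers.itertuples(index=False)):
            calls = []
            for i in range(geno.n_individuals):
                d = geno.dosages[i, j]
                gt = "./." if np.isnan(d) else gt_codes[int(round(d))]
                dp = "." if depth is None else str(int(depth[i, j]))
                calls.append(f"{gt}:{dp}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\t"
                "GT:DP\t" + "\t".join(calls) + "\n"
            )


def load_fixture(fixture_dir) -> dict:
    """Read back a fixture directory written by :func:`write_fixture`."""
    fixture_dir = Path(fixture_dir)
    out = {"geno": read_vcf(fixture_dir / "genotypes.vcf")}
    pheno = pd.read_csv(fixture_dir / "phenotypes.csv", index_col="id")
    out["pheno"] = pheno["value"].rename("trait")
    labels_path = fixture_dir / "subpops.csv"
    if labels_path.exists():
        out["labels"] = pd.read_csv(labels_path)["subpop"].to_numpy()
    truth_path = fixture_dir / "truth.json"
    if truth_path.exists():
        out["truth"] = json.loads(truth_path.read_text())
    return out
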