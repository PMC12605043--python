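"""Genotype I/O and quality control.

Reads diploid VCF genotypes into an individuals x markers dosage matrix
(alt-allele counts 0/1/2, NaN for missing) and applies the standard
sequence-data QC cascade: per-call depth masking, per-marker missingness,
mean depth, minor allele frequency and Hardy-Weinberg equilibrium filters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "QCError",
    "VCFError",
    "read_vcf",
    "apply_qc_filters",
    "hwe_exact_test",
    "mean_impute",
    "encode_blush_scale",
    "BLUSH_SCALE",
]


class VCFError(ValueError):
    """Raised for malformed or unsupported VCF input."""


class QCError(ValueError):
    """Raised when QC removes every marker; carries the QCReport."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with a marker map.

    Attributes
    ----------
    ids : ndarray of str
        Individual identifiers (unique).
    markers : DataFrame
        One row per marker with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``, ``id``; sorted by (chrom, pos) within chromosome.
    dosages : ndarray, shape (n, m)
        Alt-allele dosage per call in {0, 1, 2}; NaN marks a missing call.
        Downstream steps (imputation) may introduce fractional dosages.
    depth : ndarray or None
        Per-call read depth, same shape as ``dosages``.
    """

    ids: np.ndarray
    markers: pd.DataFrame
    dosages: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.markers)} markers"
            )
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["id"].to_numpy()

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker from non-missing calls."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def marker_index(self, marker_ids) -> np.ndarray:
        """Positional indices of the given marker ids (order preserved)."""
        lookup = pd.Index(self.markers["id"])
        idx = lookup.get_indexer(list(marker_ids))
        if (idx < 0).any():
            missing = [m for m, i in zip(marker_ids, idx) if i < 0]
            raise KeyError(f"markers not present: {missing[:5]}")
        return idx

    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        """Subset by individual ids and/or marker ids (or boolean masks)."""
        rows = np.arange(self.n_individuals)
        if individuals is not None:
            individuals = np.asarray(individuals)
            if individuals.dtype == bool:
                rows = np.flatnonzero(individuals)
            else:
                lookup = {v: i for i, v in enumerate(self.ids)}
                try:
                    rows = np.array([lookup[v] for v in individuals])
                except KeyError as exc:
                    raise KeyError(f"individual not present: {exc}") from exc
        cols = np.arange(self.n_markers)
        if markers is not None:
            markers = np.asarray(markers)
            if markers.dtype == bool:
                cols = np.flatnonzero(markers)
            else:
                cols = self.marker_index(markers)
        return GenotypeMatrix(
            ids=self.ids[rows],
            markers=self.markers.iloc[cols],
            dosages=self.dosages[np.ix_(rows, cols)],
            depth=None if self.depth is None else self.depth[np.ix_(rows, cols)],
        )


@dataclass
class QCReport:
    """Per-stage accounting for the QC filter cascade."""

    input_markers: int = 0
    calls_masked_low_depth: int = 0
    removed_missingness: int = 0
    removed_mean_depth: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    retained: int = 0
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = (
            self.removed_missingness
            + self.removed_mean_depth
            + self.removed_maf
            + self.removed_hwe
        )
        if self.input_markers and self.retained + removed != self.input_markers:
            raise ValueError("QCReport counts do not add up")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def __str__(self) -> str:
        lines = [
            f"input markers            : {self.input_markers}",
            f"calls masked (low depth) : {self.calls_masked_low_depth}",
            f"removed: missingness     : {self.removed_missingness}",
            f"removed: mean depth      : {self.removed_mean_depth}",
            f"removed: MAF             : {self.removed_maf}",
            f"removed: HWE             : {self.removed_hwe}",
            f"retained                 : {self.retained}",
        ]
        return "\n".join(lines)


def read_vcf(path) -> GenotypeMatrix:
    """Read a diploid VCF into a :class:`GenotypeMatrix`.

    Biallelic SNPs only: multi-allelic records and indels are skipped with
    a warning. ``./.`` becomes NaN; the DP FORMAT field is captured when
    declared. Haploid calls raise :class:`VCFError`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VCFError(f"cannot parse VCF {path}: {exc}") from exc

    ids = np.array(vcf.samples, dtype=object)
    if len(ids) == 0:
        raise VCFError(f"{path}: VCF has no samples")

    rows = []
    dosage_rows = []
    depth_rows = []
    has_depth = "DP" in {f for f in _format_fields(vcf)}
    n_skipped = 0
    for line_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = v.genotype.array()  # (n, ploidy+1); last col is phasing
        if gts.shape[1] != 3:
            raise VCFError(
                f"{path}: non-diploid call at {v.CHROM}:{v.POS} (record {line_no})"
            )
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        if np.nanmax(alleles, initial=0) > 1:
            raise VCFError(
                f"{path}: allele index >1 at {v.CHROM}:{v.POS} (record {line_no})"
            )
        dos = alleles.sum(axis=1)  # NaN if either allele missing
        dosage_rows.append(dos)
        if has_depth:
            dp = v.format("DP")
            if dp is None:
                depth_rows.append(np.full(len(ids), np.nan))
            else:
                dp = dp.astype(float).reshape(-1)
                dp[dp < 0] = np.nan
                depth_rows.append(dp)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], vid))

    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} multi-allelic/indel records")
    if not rows:
        raise VCFError(f"{path}: no biallelic SNP records")

    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"])
    dosages = np.vstack(dosage_rows).T
    depth = np.vstack(depth_rows).T if depth_rows else None
    return GenotypeMatrix(ids=ids, markers=markers, dosages=dosages, depth=depth)


def _format_fields(vcf):
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                yield h["ID"]
        except KeyError:
            continue


def apply_qc_filters(
    geno: GenotypeMatrix,
    min_depth: float = 5,
    max_missing: float = 0.20,
    max_mean_depth: float = 50,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC cascade in fixed order and report per-stage counts.

    Order: (1) mask calls with depth < ``min_depth``; (2) drop markers with
    missing fraction > ``max_missing``; (3) drop markers with mean depth
    (over non-missing calls) > ``max_mean_depth``; (4) drop markers with
    MAF < ``min_maf`` (strict, from non-missing calls); (5) drop markers
    with HWE exact-test p < ``hwe_alpha``.
    """
    dosages = geno.dosages.copy()
    depth = None if geno.depth is None else geno.depth.copy()

    n_masked = 0
    if min_depth is not None and min_depth > 0:
        if depth is None:
            raise ValueError("depth filter requested but genotypes carry no depth")
        low = np.nan_to_num(depth, nan=np.inf) < min_depth
        n_masked = int((low & ~np.isnan(dosages)).sum())
        dosages[low] = np.nan

    work = GenotypeMatrix(geno.ids, geno.markers, dosages, depth)
    alive = np.ones(work.n_markers, dtype=bool)

    miss = work.missing_rate()
    drop = alive & (miss > max_missing)
    n_miss = int(drop.sum())
    alive &= ~drop

    if depth is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = np.where(np.isnan(dosages), np.nan, depth)
            mean_dp = np.nanmean(d, axis=0)
        drop = alive & (np.nan_to_num(mean_dp) > max_mean_depth)
    else:
        drop = np.zeros_like(alive)
    n_meandp = int(drop.sum())
    alive &= ~drop

    maf = work.maf()
    drop = alive & ~(np.nan_to_num(maf) >= min_maf)
    n_maf = int(drop.sum())
    alive &= ~drop

    n_hwe = 0
    for j in np.flatnonzero(alive):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        n_aa = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        if hwe_exact_test(n_aa, n_ab, n_bb) < hwe_alpha:
            alive[j] = False
            n_hwe += 1

    report = QCReport(
        input_markers=geno.n_markers,
        calls_masked_low_depth=n_masked,
        removed_missingness=n_miss,
        removed_mean_depth=n_meandp,
        removed_maf=n_maf,
        removed_hwe=n_hwe,
        retained=int(alive.sum()),
        thresholds=dict(
            min_depth=min_depth,
            max_missing=max_missing,
            max_mean_depth=max_mean_depth,
            min_maf=min_maf,
            hwe_alpha=hwe_alpha,
        ),
    )
    if not alive.any():
        raise QCError(f"all markers removed by QC:\n{report}", report=report)
    out = GenotypeMatrix(
        ids=geno.ids,
        markers=geno.markers[alive],
        dosages=dosages[:, alive],
        depth=None if depth is None else depth[:, alive],
    )
    return out, report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic marker.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote-count configurations no more probable than the
    observed one (two-sided exact test in the Wigginton/VCFtools style).
    Monomorphic markers return 1.0 by convention.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # Distribution over heterozygote counts (fixed parity with `rare`),
    # built outward from the mode by the standard ratio recurrence.
    het_probs = np.zeros(rare + 1)
    mid = int(rare * (2 * n - rare) / (2.0 * n))
    if mid % 2 != rare % 2:
        mid += 1
    het_probs[mid] = 1.0
    het = mid
    while het > 1:
        # P(het-2)/P(het) = het*(het-1) / (4*(hom_r+1)*(hom_c+1))
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        het_probs[het - 2] = (
            het_probs[het] * het * (het - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        )
        het -= 2
    het = mid
    while het <= rare - 2:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        het_probs[het + 2] = (
            het_probs[het] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        )
        het += 2
    het_probs /= het_probs.sum()

    obs = het_probs[n_Aa]
    p = het_probs[het_probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def mean_impute(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by its marker's mean dosage.

    Raises if any marker has every call missing.
    """
    miss = np.isnan(geno.dosages)
    if not miss.any():
        return geno
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = geno.markers["id"].to_numpy()[all_missing][:5]
        raise ValueError(f"markers with all calls missing: {list(bad)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(geno.dosages, axis=0)
    dosages = np.where(miss, means[None, :], geno.dosages)
    return replace(geno, dosages=dosages)


BLUSH_SCALE = {
    "no blush": 0,
    "yellow": 0,
    "no blush or yellow": 0,
    "orange": 1,
    "pink": 2,
    "pink-red": 3,
    "red": 4,
    "burgundy": 5,
}


def encode_blush_scale(labels) -> np.ndarray:
    """Encode fruit blush colour categories on the ordinal 0-5 scale.

    Least to most desirable: no blush/yellow = 0, orange = 1, pink = 2,
    pink-red = 3, red = 4, burgundy = 5. Case-insensitive.
    """
    out = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        key = str(lab).strip().lower()
        if key not in BLUSH_SCALE:
            raise ValueError(
                f"unknown blush label {lab!r}; valid labels: {sorted(BLUSH_SCALE)}"
            )
        out[i] = BLUSH_SCALE[key]
    return out
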