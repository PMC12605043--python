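"""Linkage disequilibrium: pairwise r2, sliding-window pruning, decay curves.

r2 is the squared Pearson correlation of unphased dosages (composite LD),
the appropriate statistic when haplotype phase is unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix

__all__ = ["PruneSpec", "LDDecayCurve", "r2", "prune", "ld_decay", "adjacent_r2_mean"]


@dataclass(frozen=True)
class PruneSpec:
    """Sliding-window pruning parameters (window/step in SNP counts)."""

    window_size: int = 15
    step: int = 10
    r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.step <= 0 or self.step > self.window_size:
            raise ValueError("need 0 < step <= window_size")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")


@dataclass
class LDDecayCurve:
    """Binned mean r2 versus physical distance."""

    bin_edges: np.ndarray  # length n_bins + 1, bp
    mean_r2: np.ndarray  # NaN where a bin holds no pairs
    n_pairs: np.ndarray
    threshold: float
    crossing_bp: float | None  # distance where mean r2 first drops below

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                bin_start=self.bin_edges[:-1],
                bin_end=self.bin_edges[1:],
                mean_r2=self.mean_r2,
                n_pairs=self.n_pairs,
            )
        )


def r2(x, y) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Pairwise-complete observations are used; returns NaN (with a warning)
    when either vector is constant over the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        warnings.warn("r2 undefined for constant or empty vectors")
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def _corr_sq(D: np.ndarray) -> np.ndarray:
    """Pairwise squared correlation between columns (complete data)."""
    Z = D - D.mean(axis=0)
    sd = Z.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(sd > 0, Z / sd, np.nan)
    C = (Z.T @ Z) / D.shape[0]
    return np.clip(C * C, 0.0, 1.0)


def prune(geno: GenotypeMatrix, spec: PruneSpec = PruneSpec()) -> list:
    """Greedy within-window LD pruning; returns retained marker ids.

    Windows of ``window_size`` SNPs advance by ``step`` along each
    chromosome (positions must be sorted within chromosome). Within a
    window, while any retained pair has r2 above the threshold, the pair
    with the largest r2 loses its lower-MAF member (positional tie-break:
    the larger position goes). Deterministic; markers with undefined r2
    (monomorphic) are never removed on LD grounds.
    """
    dosages = geno.dosages
    maf = geno.maf()
    pos = geno.markers["pos"].to_numpy()
    keep = np.ones(geno.n_markers, dtype=bool)
    for _, idx in _chromosome_blocks(geno):
        if np.any(np.diff(pos[idx]) < 0):
            raise ValueError("markers must be position-sorted within chromosome")
        # windows slide over the *currently retained* markers; repeat until
        # a full pass removes nothing, so no retained window holds a pair
        # above the threshold
        while True:
            retained = idx[keep[idx]]
            before = len(retained)
            for start in range(0, len(retained), spec.step):
                win = retained[start : start + spec.window_size]
                if len(win) < 2:
                    continue
                _prune_window(dosages, maf, pos, win, keep, spec)
                if start + spec.window_size >= len(retained):
                    break
            if int(keep[idx].sum()) == before:
                break
    return list(geno.markers["id"].to_numpy()[keep])


def _prune_window(dosages, maf, pos, win, keep, spec) -> None:
    active = win[keep[win]]
    if len(active) < 2:
        return
    C = _corr_sq(dosages[:, active])
    np.fill_diagonal(C, 0.0)
    C = np.nan_to_num(C)
    alive = np.ones(len(active), dtype=bool)
    while True:
        sub = C[np.ix_(alive, alive)]
        if sub.size == 0 or np.nanmax(sub) <= spec.r2_threshold:
            break
        local = np.flatnonzero(alive)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = local[i], local[j]
        ga, gb = active[a], active[b]
        if maf[ga] < maf[gb]:
            victim = a
        elif maf[gb] < maf[ga]:
            victim = b
        else:
            victim = a if pos[ga] > pos[gb] else b
        alive[victim] = False
    keep[active[~alive]] = False


def _chromosome_blocks(geno: GenotypeMatrix):
    chrom = geno.markers["chrom"].to_numpy()
    _, starts = np.unique(chrom, return_index=True)
    for s in np.sort(starts):
        c = chrom[s]
        idx = np.flatnonzero(chrom == c)
        yield c, idx


def ld_decay(
    geno: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    bin_width_bp: int = 1_000,
    threshold: float = 0.2,
) -> LDDecayCurve:
    """Bin intra-chromosomal pairwise r2 by physical distance.

    The crossing distance is where the binned curve first drops below
    ``threshold``: the left edge if already below in the first occupied
    bin, otherwise linear interpolation between adjacent bin midpoints.
    Missing (None) when the curve never crosses.
    """
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    edges = np.arange(n_bins + 1) * bin_width_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    pos_all = geno.markers["pos"].to_numpy()
    any_pair = False
    for _, idx in _chromosome_blocks(geno):
        if len(idx) < 2:
            continue
        C = _corr_sq(geno.dosages[:, idx])
        pos = pos_all[idx].astype(float)
        iu, ju = np.triu_indices(len(idx), k=1)
        dist = np.abs(pos[ju] - pos[iu])
        val = C[iu, ju]
        ok = (dist <= max_dist_bp) & ~np.isnan(val)
        if not ok.any():
            continue
        any_pair = True
        b = np.minimum((dist[ok] / bin_width_bp).astype(int), n_bins - 1)
        np.add.at(sums, b, val[ok])
        np.add.at(counts, b, 1)
    if not any_pair:
        raise ValueError("no marker pairs within max_dist_bp")

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    crossing = _crossing_distance(edges, means, threshold)
    return LDDecayCurve(
        bin_edges=edges,
        mean_r2=means,
        n_pairs=counts,
        threshold=threshold,
        crossing_bp=crossing,
    )


def _crossing_distance(edges, means, threshold):
    occ = np.flatnonzero(~np.isnan(means))
    below = occ[means[occ] < threshold]
    if below.size == 0:
        return None
    k = below[0]
    prev = occ[occ < k]
    mids = (edges[:-1] + edges[1:]) / 2.0
    if prev.size == 0:
        return float(edges[k])
    j = prev[-1]
    # linear interpolation between the midpoints of bins j and k
    frac = (means[j] - threshold) / (means[j] - means[k])
    return float(mids[j] + frac * (mids[k] - mids[j]))


def adjacent_r2_mean(geno: GenotypeMatrix) -> float:
    """Mean r2 of consecutive marker pairs, averaged genome-wide.

    Pairs with undefined r2 (monomorphic member) are skipped; raises if
    no chromosome has two markers.
    """
    vals = []
    for _, idx in _chromosome_blocks(geno):
        if len(idx) < 2:
            continue
        D = geno.dosages[:, idx]
        Z = D - np.nanmean(D, axis=0)
        sd = np.nanstd(D, axis=0)
        for a in range(len(idx) - 1):
            if sd[a] == 0 or sd[a + 1] == 0:
                continue
            x, y = D[:, a], D[:, a + 1]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            vals.append(min(r * r, 1.0))
    if not vals:
        raise ValueError("no adjacent marker pairs with defined r2")
    return float(np.mean(vals))
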