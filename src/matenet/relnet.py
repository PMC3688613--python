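"""Pairwise relatedness estimation, threshold calibration, and the
relatedness network.

The estimator is the Queller-Goodnight moment (ratio) estimator: per
ordered pair, locus-wise numerators and denominators are summed over
loci before division, and the two directions are averaged so that
r(i, j) = r(j, i) exactly.  With true allele frequencies the estimator
is unbiased: ~0 for unrelated dyads, ~0.25 for half-sibs, ~0.5 for
full-sibs.

The relatedness threshold is calibrated empirically as the maximum
estimate observed among known-unrelated offspring pairs (pairs sharing
neither parent); adults above the threshold are linked in the
relatedness network.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .simstand import MISSING

logger = logging.getLogger("matenet.relnet")

#: Threshold used when no calibration pairs are available.
DEFAULT_THRESHOLD = 0.22


@dataclasses.dataclass
class RelatednessMatrix:
    """Symmetric pairwise relatedness estimates among named individuals."""

    ids: list[str]
    values: np.ndarray  # (n, n), NaN where undefined; diagonal unused (NaN)
    n_loci: np.ndarray  # (n, n) informative locus counts

    def pair(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])


@dataclasses.dataclass
class ThresholdCalibration:
    threshold: float
    n_unrelated_pairs: int
    max_unrelated: float
    summaries: dict[str, dict[str, float]]


def allele_frequencies(genotypes: np.ndarray, allele_counts: Sequence[int]) -> list[np.ndarray]:
    """Sample allele frequencies per locus, ignoring missing data."""
    L = genotypes.shape[1]
    out = []
    for l in range(L):
        alleles = genotypes[:, l, :].ravel()
        alleles = alleles[alleles != MISSING]
        counts = np.bincount(alleles, minlength=allele_counts[l]).astype(float)
        if counts.sum() == 0:
            raise ValueError(f"no genotyped individual at locus {l}")
        out.append(counts / counts.sum())
    return out


def _qg_locus_terms(ax, bx, ay, by, pax, pbx):
    """Queller-Goodnight numerator/denominator for direction x -> y.

    Arrays broadcast; identity indicators are exact integer comparisons.
    """
    num = 0.5 * (
        (ax == ay).astype(float)
        + (ax == by).astype(float)
        + (bx == ay).astype(float)
        + (bx == by).astype(float)
    ) - pax - pbx
    den = 1.0 + (ax == bx).astype(float) - pax - pbx
    return num, den


def relatedness_dyads(
    g1: np.ndarray,
    g2: np.ndarray,
    allele_freqs: Sequence[np.ndarray],
    min_loci: int = 1,
) -> np.ndarray:
    """Symmetrized Queller-Goodnight estimates for matched dyad arrays.

    ``g1`` and ``g2`` are ``(m, L, 2)`` genotype arrays; element k of the
    result is the relatedness of pair (g1[k], g2[k]).
    """
    m, L, _ = g1.shape
    num12 = np.zeros(m)
    den12 = np.zeros(m)
    num21 = np.zeros(m)
    den21 = np.zeros(m)
    nl = np.zeros(m, dtype=int)
    for l in range(L):
        f = allele_freqs[l]
        a1, b1 = g1[:, l, 0], g1[:, l, 1]
        a2, b2 = g2[:, l, 0], g2[:, l, 1]
        ok = (a1 != MISSING) & (b1 != MISSING) & (a2 != MISSING) & (b2 != MISSING)
        if not ok.any():
            continue
        pa1 = np.where(ok, f[np.where(ok, a1, 0)], 0.0)
        pb1 = np.where(ok, f[np.where(ok, b1, 0)], 0.0)
        pa2 = np.where(ok, f[np.where(ok, a2, 0)], 0.0)
        pb2 = np.where(ok, f[np.where(ok, b2, 0)], 0.0)
        n12, d12 = _qg_locus_terms(a1, b1, a2, b2, pa1, pb1)
        n21, d21 = _qg_locus_terms(a2, b2, a1, b1, pa2, pb2)
        num12 += np.where(ok, n12, 0.0)
        den12 += np.where(ok, d12, 0.0)
        num21 += np.where(ok, n21, 0.0)
        den21 += np.where(ok, d21, 0.0)
        nl += ok.astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 0.5 * (num12 / den12 + num21 / den21)
    r = np.where((nl >= min_loci) & np.isfinite(r), r, np.nan)
    return r


def estimate_relatedness(
    genotypes: Mapping[str, np.ndarray],
    allele_freqs: Sequence[np.ndarray],
    estimator: str = "queller-goodnight",
    min_loci: int = 6,
) -> RelatednessMatrix:
    """All-pairs symmetrized Queller-Goodnight relatedness matrix.

    Pairs sharing fewer than ``min_loci`` jointly genotyped loci, or with
    a zero summed denominator, are left undefined (NaN).
    """
    if estimator not in {"queller-goodnight", "qg"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    ids = list(genotypes)
    g = np.stack([genotypes[i] for i in ids])  # (n, L, 2)
    n, L, _ = g.shape
    num = np.zeros((n, n))  # numerator of direction row -> col
    den = np.zeros((n, n))
    nl = np.zeros((n, n), dtype=int)
    for l in range(L):
        f = allele_freqs[l]
        a, b = g[:, l, 0], g[:, l, 1]
        ok = (a != MISSING) & (b != MISSING)
        pa = np.where(ok, f[np.where(ok, a, 0)], 0.0)
        pb = np.where(ok, f[np.where(ok, b, 0)], 0.0)
        ax, bx = a[:, None], b[:, None]
        ay, by = a[None, :], b[None, :]
        nmat, dmat = _qg_locus_terms(ax, bx, ay, by, pa[:, None], pb[:, None])
        both = ok[:, None] & ok[None, :]
        num += np.where(both, nmat, 0.0)
        den += np.where(both, dmat, 0.0)
        nl += both.astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_dir = num / den
    r = 0.5 * (r_dir + r_dir.T)
    bad = (nl < min_loci) | ~np.isfinite(r)
    n_zero_den = int(((den == 0) | (den.T == 0))[np.triu_indices(n, 1)].sum())
    if n_zero_den:
        logger.warning("%d pairs dropped for zero summed denominator", n_zero_den)
    r[bad] = np.nan
    np.fill_diagonal(r, np.nan)
    return RelatednessMatrix(ids=ids, values=r, n_loci=nl)


def _summary(values: np.ndarray) -> dict[str, float]:
    v = values[np.isfinite(values)]
    qs = np.quantile(v, [0.05, 0.25, 0.5, 0.75, 0.95]) if v.size else [np.nan] * 5
    return {
        "n": int(v.size),
        "mean": float(np.mean(v)) if v.size else float("nan"),
        "min": float(np.min(v)) if v.size else float("nan"),
        "max": float(np.max(v)) if v.size else float("nan"),
        "q05": float(qs[0]),
        "q25": float(qs[1]),
        "median": float(qs[2]),
        "q75": float(qs[3]),
        "q95": float(qs[4]),
    }


def calibrate_threshold(
    relmatrix: RelatednessMatrix,
    unrelated_pairs: Sequence[tuple[str, str]],
    half_sib_pairs: Sequence[tuple[str, str]] | None = None,
    full_sib_pairs: Sequence[tuple[str, str]] | None = None,
) -> ThresholdCalibration:
    """Set the relatedness threshold from known-unrelated pairs.

    The threshold is the maximum estimate over the unrelated calibration
    set (pairs of offspring sharing neither parent); optional half-sib /
    full-sib pair sets are summarized for validation only.
    """
    def values_for(pairs):
        idx = {i: k for k, i in enumerate(relmatrix.ids)}
        out = []
        for i, j in pairs:
            v = relmatrix.values[idx[i], idx[j]]
            if np.isfinite(v):
                out.append(v)
        return np.array(out)

    vals = values_for(unrelated_pairs)
    if vals.size == 0:
        raise ValueError(
            "no unrelated calibration pair with a defined estimate; "
            f"use the fallback default threshold {DEFAULT_THRESHOLD}"
        )
    summaries = {"unrelated": _summary(vals)}
    if half_sib_pairs is not None:
        summaries["half_sib"] = _summary(values_for(half_sib_pairs))
    if full_sib_pairs is not None:
        summaries["full_sib"] = _summary(values_for(full_sib_pairs))
    threshold = float(np.max(vals))
    return ThresholdCalibration(
        threshold=threshold,
        n_unrelated_pairs=int(vals.size),
        max_unrelated=threshold,
        summaries=summaries,
    )


def build_relatedness_network(relmatrix: RelatednessMatrix, threshold: float) -> nx.Graph:
    """Link individuals whose estimate is strictly above the threshold.

    Undefined (NaN) pairs yield no edge.  Nodes are individuals incident
    to at least one edge; ids left isolated are reported in
    ``graph.graph["isolated_ids"]``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    g = nx.Graph()
    n = len(relmatrix.ids)
    iu, ju = np.triu_indices(n, 1)
    vals = relmatrix.values[iu, ju]
    keep = np.isfinite(vals) & (vals > threshold)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(relmatrix.ids[i], relmatrix.ids[j])
    g.graph["threshold"] = float(threshold)
    g.graph["isolated_ids"] = [i for i in relmatrix.ids if i not in g]
    return g
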