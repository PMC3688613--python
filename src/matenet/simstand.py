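"""Synthetic two-species forest stand with open-pollinated mating.

This module generates the kind of data the downstream network analyses
assume: a mixed stand of two hybridizing, wind-pollinated tree species
(think of a ~5 ha oak stand with a few hundred adults), genotyped at a
multiplexed panel of codominant microsatellite (SSR) loci.  Mating is
simulated under open pollination with a distance-decaying pollen
dispersal kernel, partial interspecific compatibility, and pollen
immigration from outside the stand.  A subset of mothers is sampled for
progeny, mirroring a real progeny test where seeds can only be harvested
from some of the trees.

All randomness flows through :class:`numpy.random.Generator` objects
derived from a single integer seed, so identical seeds reproduce stands
and progenies exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

#: Token used for fathers outside the stand (pollen immigration).
EXTERNAL = "EXTERNAL"

SPECIES = ("A", "B")

MISSING = -1


class DegenerateParameterError(ValueError):
    """Raised when simulation parameters leave no eligible father."""


@dataclasses.dataclass
class Stand:
    """Adult trees of a mixed stand.

    Attributes
    ----------
    ids
        Unique individual identifiers, one per adult.
    coords
        ``(n, 2)`` planar coordinates in meters, within ``extent``.
    species
        ``(n,)`` array of latent species labels, ``"A"`` or ``"B"``.
    genotypes
        ``(n, n_loci, 2)`` integer allele ids; ``-1`` marks missing data.
    extent
        ``(width, height)`` of the rectangular stand in meters.
    allele_counts
        Number of alleles segregating at each locus.
    allele_freqs
        Mapping species -> list of per-locus allele frequency vectors.
    """

    ids: list[str]
    coords: np.ndarray
    species: np.ndarray
    genotypes: np.ndarray
    extent: tuple[float, float]
    allele_counts: np.ndarray
    allele_freqs: dict[str, list[np.ndarray]]

    @property
    def n_adults(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def index_of(self, individual_id: str) -> int:
        return self.ids.index(individual_id)

    def pooled_freqs(self) -> list[np.ndarray]:
        """Species-abundance-weighted allele frequencies per locus."""
        n = self.n_adults
        weights = {s: np.mean(self.species == s) for s in SPECIES}
        out = []
        for l in range(self.n_loci):
            f = np.zeros(self.allele_counts[l])
            for s in SPECIES:
                if weights[s] > 0:
                    f += weights[s] * self.allele_freqs[s][l]
            out.append(f / f.sum())
        return out

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "species": self.species,
            }
        )

    def validate(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        w, h = self.extent
        if np.any(self.coords < 0) or np.any(self.coords[:, 0] > w) or np.any(self.coords[:, 1] > h):
            raise ValueError("coordinates outside stand extent")
        for s in SPECIES:
            for l, f in enumerate(self.allele_freqs[s]):
                if abs(f.sum() - 1.0) > 1e-9:
                    raise ValueError(f"allele frequencies at locus {l} do not sum to 1")


@dataclasses.dataclass
class OffspringRecord:
    """One open-pollinated offspring with its known pedigree truth."""

    offspring_id: str
    mother_id: str
    true_father_id: str  # adult id or EXTERNAL
    genotype: np.ndarray  # (n_loci, 2)


def generate_stand(
    n_A: int,
    n_B: int,
    n_loci: int = 12,
    alleles_per_locus: int = 10,
    differentiation: float = 0.8,
    extent: tuple[float, float] = (200.0, 250.0),
    species_clustering: float = 0.75,
    seed: int | None = None,
) -> Stand:
    """Generate a mixed stand of two species.

    Positions are uniform over the rectangular extent.  Species labels
    are spatially autocorrelated: individuals are ranked by a score mixing
    their position along the stand's long axis with uniform noise, and the
    top ``n_A`` ranks become species A.  ``species_clustering`` in [0, 1]
    moves from a well-mixed stand (0) to a hard spatial split (1); mixed
    stands of related, hybridizing trees are typically strongly segregated
    with a mixed contact zone, hence the default 0.75.

    Per-locus allele frequencies for the two species start from a shared
    Dirichlet draw and are mixed toward opposite allele-rank orderings of
    that draw; the ``differentiation`` parameter in [0, 1] therefore
    interpolates from identical frequency spectra (0) to strongly
    divergent ones (1).  Genotypes are drawn independently per locus from
    the individual's species frequencies (Hardy-Weinberg, no linkage).
    """
    if n_A + n_B < 2:
        raise ValueError("need at least two adults")
    if n_A < 0 or n_B < 0:
        raise ValueError("negative species count")
    if not 0.0 <= differentiation <= 1.0:
        raise ValueError("differentiation must be in [0, 1]")
    if extent[0] <= 0 or extent[1] <= 0:
        raise ValueError("extent must be positive")
    if n_loci < 1 or alleles_per_locus < 2:
        raise ValueError("need >=1 locus with >=2 alleles")
    if not 0.0 <= species_clustering <= 1.0:
        raise ValueError("species_clustering must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n = n_A + n_B
    ids = [f"t{i + 1:03d}" for i in range(n)]
    coords = rng.uniform([0, 0], list(extent), size=(n, 2))
    axis = int(np.argmax(extent))
    score = (species_clustering * coords[:, axis] / extent[axis]
             + (1.0 - species_clustering) * rng.random(n))
    species = np.full(n, "B")
    species[np.argsort(score)[::-1][:n_A]] = "A"

    d = differentiation
    freqs: dict[str, list[np.ndarray]] = {"A": [], "B": []}
    for _ in range(n_loci):
        base = rng.dirichlet(np.ones(alleles_per_locus))
        desc = np.sort(base)[::-1]
        asc = np.sort(base)
        fA = (1 - d) * base + d * desc
        fB = (1 - d) * base + d * asc
        freqs["A"].append(fA / fA.sum())
        freqs["B"].append(fB / fB.sum())

    genotypes = np.empty((n, n_loci, 2), dtype=np.int16)
    for l in range(n_loci):
        for s, mask in (("A", species == "A"), ("B", species == "B")):
            k = int(mask.sum())
            if k:
                genotypes[mask, l, :] = rng.choice(
                    alleles_per_locus, size=(k, 2), p=freqs[s][l]
                )

    stand = Stand(
        ids=ids,
        coords=coords,
        species=species,
        genotypes=genotypes,
        extent=tuple(float(e) for e in extent),
        allele_counts=np.full(n_loci, alleles_per_locus, dtype=int),
        allele_freqs=freqs,
    )
    stand.validate()
    return stand


def _gamete(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One uniformly chosen allele per locus; missing propagates."""
    picks = rng.integers(0, 2, size=genotype.shape[0])
    return genotype[np.arange(genotype.shape[0]), picks]


def _random_gamete(freqs: Sequence[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    return np.array([rng.choice(len(f), p=f) for f in freqs], dtype=np.int16)


def mendelian_offspring(
    mother: np.ndarray,
    father: np.ndarray,
    error_rate: float = 0.0,
    seed: int | None = None,
    locus_freqs: Sequence[np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw an offspring genotype from two parental genotypes.

    One uniformly chosen allele per parent per locus; with probability
    ``error_rate`` each transmitted allele is replaced by a random allele
    drawn from the locus frequency vector (a crude genotyping-error /
    mutation model).  ``locus_freqs`` is required whenever
    ``error_rate > 0``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if error_rate > 0 and locus_freqs is None:
        raise ValueError("locus_freqs required when error_rate > 0")
    maternal = _gamete(mother, rng)
    paternal = _gamete(father, rng)
    out = np.stack([maternal, paternal], axis=1).astype(np.int16)
    if error_rate > 0:
        err = rng.random(out.shape) < error_rate
        for l in range(out.shape[0]):
            for a in range(2):
                if err[l, a] and out[l, a] != MISSING:
                    f = locus_freqs[l]
                    out[l, a] = rng.choice(len(f), p=f)
    return out


def simulate_mating(
    stand: Stand,
    n_mothers: int = 51,
    offspring_per_mother: int = 60,
    dispersal_scale: float = 69.0,
    compatibility: float = 0.2,
    immigration: float = 0.45,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> list[OffspringRecord]:
    """Simulate open-pollinated progenies for a sampled set of mothers.

    Mothers are sampled without replacement.  For each offspring, with
    probability ``immigration`` the father is outside the stand
    (``EXTERNAL``; the paternal gamete is drawn from species-level allele
    frequencies, with the external father's species drawn according to
    stand composition).  Otherwise an in-stand father j != mother is drawn
    with weight ``exp(-d_ij / dispersal_scale)`` times 1 for conspecific
    pairs and ``compatibility`` for heterospecific pairs.  Selfing is
    excluded.
    """
    for name, v in (("compatibility", compatibility), ("immigration", immigration), ("error_rate", error_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if dispersal_scale <= 0:
        raise ValueError("dispersal_scale must be positive")
    if n_mothers > stand.n_adults:
        raise ValueError("more mothers than adults")

    rng = np.random.default_rng(seed)
    n = stand.n_adults
    mothers = rng.choice(n, size=n_mothers, replace=False)
    pooled = stand.pooled_freqs()
    species_prop = {s: float(np.mean(stand.species == s)) for s in SPECIES}

    records: list[OffspringRecord] = []
    counter = 0
    for mi in mothers:
        d = np.linalg.norm(stand.coords - stand.coords[mi], axis=1)
        w = np.exp(-d / dispersal_scale)
        w *= np.where(stand.species == stand.species[mi], 1.0, compatibility)
        w[mi] = 0.0  # no selfing
        total = w.sum()
        if total == 0 and immigration < 1.0:
            raise DegenerateParameterError(
                f"no eligible father for mother {stand.ids[mi]}; "
                "check compatibility/dispersal parameters"
            )
        p = w / total if total > 0 else None
        for _ in range(offspring_per_mother):
            counter += 1
            oid = f"o{counter:05d}"
            if rng.random() < immigration:
                sp = "A" if rng.random() < species_prop["A"] else "B"
                paternal = _random_gamete(stand.allele_freqs[sp], rng)
                maternal = _gamete(stand.genotypes[mi], rng)
                geno = np.stack([maternal, paternal], axis=1).astype(np.int16)
                if error_rate > 0:
                    err = rng.random(geno.shape) < error_rate
                    for l in range(stand.n_loci):
                        for a in range(2):
                            if err[l, a] and geno[l, a] != MISSING:
                                geno[l, a] = rng.choice(len(pooled[l]), p=pooled[l])
                father_id = EXTERNAL
            else:
                fi = rng.choice(n, p=p)
                geno = mendelian_offspring(
                    stand.genotypes[mi],
                    stand.genotypes[fi],
                    error_rate=error_rate,
                    locus_freqs=pooled,
                    rng=rng,
                )
                father_id = stand.ids[fi]
            records.append(
                OffspringRecord(
                    offspring_id=oid,
                    mother_id=stand.ids[mi],
                    true_father_id=father_id,
                    genotype=geno,
                )
            )
    return records


def hybrid_index(stand: Stand, genotypes: np.ndarray | None = None) -> np.ndarray:
    """Maximum-likelihood admixture proportion toward species A.

    For each individual the index q maximizes the likelihood of its
    alleles under the two-species mixture ``q * fA + (1 - q) * fB``,
    treating alleles as independent draws.  Purebreds sit near 1
    (species A) or 0 (species B); F1 hybrids concentrate around 0.5.
    The maximizer is located on a fine grid (the per-individual
    log-likelihood is concave in q).
    """
    g = stand.genotypes if genotypes is None else genotypes
    n = g.shape[0]
    # per-allele frequencies under each species, flattened over (locus, slot)
    pA = np.full((n, stand.n_loci * 2), np.nan)
    pB = np.full((n, stand.n_loci * 2), np.nan)
    for l in range(stand.n_loci):
        fA = stand.allele_freqs["A"][l]
        fB = stand.allele_freqs["B"][l]
        for slot in range(2):
            al = g[:, l, slot]
            ok = al != MISSING
            col = 2 * l + slot
            pA[ok, col] = fA[al[ok]]
            pB[ok, col] = fB[al[ok]]
    qs = np.linspace(0.0, 1.0, 1001)
    idx = np.full(n, np.nan)
    valid = ~np.isnan(pA)
    for i in range(n):
        v = valid[i]
        if not v.any():
            continue
        mix = np.outer(qs, pA[i, v]) + np.outer(1.0 - qs, pB[i, v])
        ll = np.log(np.maximum(mix, 1e-300)).sum(axis=1)
        idx[i] = qs[int(np.argmax(ll))]
    return idx


def synthetic_reference_assignments(
    stand: Stand,
    trait_noise: float = 0.1,
    hybrid_thresholds: tuple[float, float] = (0.2, 0.8),
    seed: int | None = None,
) -> pd.DataFrame:
    """Genotype-like and morphology-like species assignments.

    Stands in for external assignment pipelines: the *genotype* criterion
    thresholds a likelihood-weighted hybrid index at
    ``hybrid_thresholds = (low, high)`` (above ``high`` -> S1 = species A,
    below ``low`` -> S2, middle band -> intermediate); the *morphology*
    criterion thresholds a 1-D trait (species means 0 for A, 1 for B,
    Gaussian noise ``trait_noise``) with the same two cutpoints.

    The hybrid index is a maximum-likelihood admixture proportion, so
    purebreds pile up at the 0/1 boundaries while F1 hybrids concentrate
    near 0.5; the default band (0.2, 0.8) is the classic hybrid-index
    purebred cutoff.

    Returns a DataFrame indexed by individual id with columns
    ``genotype`` and ``morphology`` taking values in
    ``{"S1", "S2", "intermediate"}``.
    """
    low, high = hybrid_thresholds
    if not 0.0 <= low < high <= 1.0:
        raise ValueError("hybrid_thresholds must satisfy 0 <= low < high <= 1")
    rng = np.random.default_rng(seed)

    h = hybrid_index(stand)
    geno = np.where(h > high, "S1", np.where(h < low, "S2", "intermediate"))

    trait = np.where(stand.species == "A", 0.0, 1.0)
    trait = trait + rng.normal(0.0, trait_noise, size=stand.n_adults)
    morph = np.where(trait <= low, "S1", np.where(trait >= high, "S2", "intermediate"))

    return pd.DataFrame({"genotype": geno, "morphology": morph}, index=pd.Index(stand.ids, name="id"))
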