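"""Exclusion-based paternity assignment and mating-network construction.

Fathers are assigned by multilocus exclusion: at each locus the feasible
paternal allele set is what remains of the offspring genotype after
subtracting one maternal contribution, and a candidate is excluded once
he fails to carry a feasible paternal allele at more than
``max_mismatch`` loci.  Offspring with exactly one surviving candidate
("single") define mating events; each unique unordered (mother, father)
pair becomes one link of the undirected, unweighted mating network.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .simstand import EXTERNAL, MISSING, OffspringRecord, Stand

logger = logging.getLogger("matenet.pedigree")


@dataclasses.dataclass
class PaternityAssignment:
    offspring_id: str
    category: str  # "single" | "multiple" | "none"
    father_id: str | None
    n_compatible: int
    mismatches_allowed: int
    mother_incompatible: bool = False

    def __post_init__(self) -> None:
        if self.category == "single" and self.n_compatible != 1:
            raise ValueError("single category requires exactly one compatible candidate")
        if self.category == "none" and self.n_compatible != 0:
            raise ValueError("none category requires zero compatible candidates")


def _feasible_paternal(offspring_locus: np.ndarray, mother_locus: np.ndarray) -> tuple[set[int], bool]:
    """Feasible paternal alleles at one locus, plus mother-mismatch flag.

    If the offspring shares both alleles with the mother either one may be
    paternal; if it shares exactly one, the other is paternal; if neither,
    the locus is a mother-offspring mismatch.
    """
    a, b = int(offspring_locus[0]), int(offspring_locus[1])
    m = {int(mother_locus[0]), int(mother_locus[1])}
    a_in, b_in = a in m, b in m
    if a_in and b_in:
        return {a, b}, False
    if a_in:
        return {b}, False
    if b_in:
        return {a}, False
    return set(), True


def exclusion_paternity(
    offspring: np.ndarray,
    mother: np.ndarray,
    candidates: Mapping[str, np.ndarray],
    max_mismatch: int = 0,
    offspring_id: str = "offspring",
) -> PaternityAssignment:
    """Assign a father to one offspring by multilocus exclusion.

    Loci with missing data in offspring or mother are skipped entirely;
    loci missing in a candidate are skipped for that candidate only.
    A mother-offspring incompatibility at more than ``max_mismatch`` loci
    flags the record as a pedigree error (excluded downstream).
    """
    n_loci = offspring.shape[0]
    feasible: list[set[int] | None] = []
    mother_mismatches = 0
    for l in range(n_loci):
        if MISSING in offspring[l] or MISSING in mother[l]:
            feasible.append(None)
            continue
        feas, mismatch = _feasible_paternal(offspring[l], mother[l])
        if mismatch:
            mother_mismatches += 1
            feasible.append(None)
        else:
            feasible.append(feas)

    if mother_mismatches > max_mismatch:
        logger.warning("offspring %s incompatible with its mother at %d loci", offspring_id, mother_mismatches)
        return PaternityAssignment(
            offspring_id, "none", None, 0, max_mismatch, mother_incompatible=True
        )

    compatible: list[str] = []
    for cid, geno in candidates.items():
        mism = 0
        for l in range(n_loci):
            feas = feasible[l]
            if feas is None or MISSING in geno[l]:
                continue
            if int(geno[l, 0]) not in feas and int(geno[l, 1]) not in feas:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            compatible.append(cid)

    if len(compatible) == 1:
        return PaternityAssignment(offspring_id, "single", compatible[0], 1, max_mismatch)
    if len(compatible) > 1:
        return PaternityAssignment(offspring_id, "multiple", None, len(compatible), max_mismatch)
    return PaternityAssignment(offspring_id, "none", None, 0, max_mismatch)


def assign_paternity(
    offspring_records: Iterable[OffspringRecord],
    stand: Stand,
    max_mismatch: int = 0,
    exclude_mother: bool = True,
) -> list[PaternityAssignment]:
    """Vectorized exclusion paternity for a whole progeny array.

    Candidates are all adults of the stand except the offspring's mother
    (selfing excluded from the candidate pool when ``exclude_mother``).
    """
    records = list(offspring_records)
    g = stand.genotypes  # (n, L, 2)
    n, L, _ = g.shape
    K = int(stand.allele_counts.max())
    lidx = np.arange(L)[None, :]
    cand_evaluable = (g != MISSING).all(axis=2)  # (n, L)
    # allele-id lookups with missing redirected to an always-False column K
    a0 = np.where(g[:, :, 0] == MISSING, K, g[:, :, 0])
    a1 = np.where(g[:, :, 1] == MISSING, K, g[:, :, 1])

    mother_index = {mid: stand.index_of(mid) for mid in {r.mother_id for r in records}}
    out: list[PaternityAssignment] = []
    for rec in records:
        mi = mother_index[rec.mother_id]
        mom = stand.genotypes[mi]
        feas_mask = np.zeros((L, K + 1), dtype=bool)
        locus_ok = np.zeros(L, dtype=bool)
        mother_mismatches = 0
        for l in range(L):
            if MISSING in rec.genotype[l] or MISSING in mom[l]:
                continue
            feas, mismatch = _feasible_paternal(rec.genotype[l], mom[l])
            if mismatch:
                mother_mismatches += 1
            else:
                locus_ok[l] = True
                for a in feas:
                    feas_mask[l, a] = True
        if mother_mismatches > max_mismatch:
            logger.warning(
                "offspring %s incompatible with its mother at %d loci",
                rec.offspring_id, mother_mismatches,
            )
            out.append(
                PaternityAssignment(rec.offspring_id, "none", None, 0, max_mismatch, True)
            )
            continue
        # compat[c, l]: candidate carries a feasible paternal allele
        compat = feas_mask[lidx, a0] | feas_mask[lidx, a1]
        evaluated = cand_evaluable & locus_ok[None, :]
        mismatches = (evaluated & ~compat).sum(axis=1)
        ok = mismatches <= max_mismatch
        if exclude_mother:
            ok[mi] = False
        n_comp = int(ok.sum())
        if n_comp == 1:
            fid = stand.ids[int(np.flatnonzero(ok)[0])]
            out.append(PaternityAssignment(rec.offspring_id, "single", fid, 1, max_mismatch))
        elif n_comp > 1:
            out.append(PaternityAssignment(rec.offspring_id, "multiple", None, n_comp, max_mismatch))
        else:
            out.append(PaternityAssignment(rec.offspring_id, "none", None, 0, max_mismatch))
    return out


def build_mating_network(
    assignments: Iterable[PaternityAssignment],
    mothers: Mapping[str, str],
) -> nx.Graph:
    """Undirected, unweighted mating network from single-father offspring.

    One edge per unique unordered (mother, father) pair; offspring with
    multiple or no compatible fathers contribute nothing; selfing pairs
    (mother == father) are dropped and counted.  Nodes are the adults
    incident to at least one edge.  Bookkeeping counts are stored in
    ``graph.graph``.
    """
    g = nx.Graph()
    n_single = n_multiple = n_none = n_selfing = n_flagged = n_events = 0
    for a in assignments:
        if a.mother_incompatible:
            n_flagged += 1
            continue
        if a.category == "multiple":
            n_multiple += 1
            continue
        if a.category == "none":
            n_none += 1
            continue
        n_single += 1
        mother = mothers[a.offspring_id]
        if mother == a.father_id:
            n_selfing += 1
            continue
        n_events += 1
        g.add_edge(mother, a.father_id)
    if n_selfing:
        logger.warning("dropped %d selfing mating events", n_selfing)
    g.graph.update(
        n_single=n_single,
        n_multiple=n_multiple,
        n_none=n_none,
        n_selfing_dropped=n_selfing,
        n_mother_incompatible=n_flagged,
        n_mating_events=n_events,
    )
    return g
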