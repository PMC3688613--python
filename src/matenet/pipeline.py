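"""End-to-end synthetic pipeline: stand -> progeny -> paternity ->
networks -> model fits -> assignments -> congruence.

Each stage is a plain function over in-memory objects so drivers (CLI,
analysis scripts, tests) stay thin.  A single integer seed fans out to
per-stage substreams in a fixed order, so a full run is reproducible
byte for byte.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd

from . import classify, congruence, csbm, pedigree, relnet, simstand
from .io import PipelineConfig


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage integer seeds from one global seed."""
    rng = np.random.default_rng(seed)
    names = ["stand", "mating", "assignments", "fit_mating", "calibration", "fit_relatedness"]
    return {name: int(rng.integers(2**31)) for name in names}


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    stand: simstand.Stand
    offspring: list[simstand.OffspringRecord]
    assignments_ref: pd.DataFrame
    paternity: list[pedigree.PaternityAssignment]
    mating_network: nx.Graph
    mating_scan: csbm.ModelScan | None
    mating_fit: csbm.CSBMFit
    mating_labels: pd.DataFrame
    relmatrix: relnet.RelatednessMatrix | None
    calibration: relnet.ThresholdCalibration | None
    relatedness_network: nx.Graph | None
    relatedness_fit: csbm.CSBMFit | None
    relatedness_labels: pd.DataFrame | None
    table: pd.DataFrame
    report: congruence.CongruenceReport
    neighborhood: congruence.NeighborhoodTest | None


def simulate_stage(config: PipelineConfig, seeds: dict[str, int]):
    stand = simstand.generate_stand(
        n_A=config.n_A,
        n_B=config.n_B,
        n_loci=config.n_loci,
        alleles_per_locus=config.alleles_per_locus,
        differentiation=config.differentiation,
        extent=config.extent,
        species_clustering=config.species_clustering,
        seed=seeds["stand"],
    )
    offspring = simstand.simulate_mating(
        stand,
        n_mothers=config.n_mothers,
        offspring_per_mother=config.offspring_per_mother,
        dispersal_scale=config.dispersal_scale,
        compatibility=config.compatibility,
        immigration=config.immigration,
        error_rate=config.error_rate,
        seed=seeds["mating"],
    )
    refs = simstand.synthetic_reference_assignments(
        stand,
        trait_noise=config.trait_noise,
        hybrid_thresholds=config.hybrid_thresholds,
        seed=seeds["assignments"],
    )
    return stand, offspring, refs


def paternity_stage(config: PipelineConfig, stand, offspring):
    assignments = pedigree.assign_paternity(offspring, stand, max_mismatch=config.max_mismatch)
    mothers = {r.offspring_id: r.mother_id for r in offspring}
    network = pedigree.build_mating_network(assignments, mothers)
    return assignments, network


def fit_stage(config: PipelineConfig, network: nx.Graph, seed: int, scan: bool = True):
    """Fit the block model; optionally scan Q and select (override wins)."""
    if scan:
        model_scan = csbm.scan_models(
            network,
            Q_min=config.Q_min,
            Q_max=config.Q_max,
            override_Q=config.override_Q,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=seed,
        )
        return model_scan, model_scan.fits[model_scan.selected_Q]
    fit = csbm.fit_csbm(
        network,
        Q=config.override_Q or 3,
        n_restarts=config.n_restarts,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=seed,
    )
    return None, fit


def relatedness_stage(config: PipelineConfig, stand, offspring, paternity, network, seed: int):
    """Relatedness among network adults, threshold calibration from
    known-pedigree offspring, and the thresholded network."""
    rng = np.random.default_rng(seed)
    adult_ids = sorted(network.nodes())
    idx = {i: k for k, i in enumerate(stand.ids)}
    freqs = relnet.allele_frequencies(stand.genotypes, stand.allele_counts)
    genotypes = {i: stand.genotypes[idx[i]] for i in adult_ids}
    relmatrix = relnet.estimate_relatedness(genotypes, freqs, min_loci=config.min_loci)

    calibration = None
    threshold = config.relatedness_threshold
    if threshold is None:
        # offspring with both parents known in the stand
        known = [(a, r) for a, r in zip(paternity, offspring) if a.category == "single"]
        parents = {
            a.offspring_id: (r.mother_id, a.father_id)
            for a, r in known
        }
        genos = {a.offspring_id: r.genotype for a, r in known}
        off_ids = list(parents)
        pairs, g1, g2 = [], [], []
        if len(off_ids) >= 2:
            tries = 0
            target = config.max_calibration_pairs
            while len(pairs) < target and tries < 50 * target:
                tries += 1
                i, j = rng.choice(len(off_ids), size=2, replace=False)
                oi, oj = off_ids[i], off_ids[j]
                if set(parents[oi]) & set(parents[oj]):
                    continue
                pairs.append((oi, oj))
                g1.append(genos[oi])
                g2.append(genos[oj])
        if pairs:
            r = relnet.relatedness_dyads(
                np.stack(g1), np.stack(g2), freqs, min_loci=config.min_loci
            )
            r = r[np.isfinite(r)]
            if r.size:
                calibration = relnet.ThresholdCalibration(
                    threshold=float(r.max()),
                    n_unrelated_pairs=int(r.size),
                    max_unrelated=float(r.max()),
                    summaries={"unrelated": relnet._summary(r)},
                )
                threshold = calibration.threshold
        if threshold is None:
            threshold = relnet.DEFAULT_THRESHOLD
    rel_network = relnet.build_relatedness_network(relmatrix, threshold)
    return relmatrix, calibration, rel_network


def congruence_stage(config: PipelineConfig, stand, mating_labels, refs, rel_labels=None):
    """Assemble the assignment table, harmonize names, summarize, and run
    the neighborhood test on the genotype/morphology-consensus subset."""
    table = refs.copy()
    table["interfertility"] = mating_labels["label"]
    if rel_labels is not None:
        table["relatedness"] = rel_labels["label"]
    table = table[[c for c in ["interfertility", "relatedness", "genotype", "morphology"] if c in table]]
    harmonized = congruence.harmonize_labels(table, reference="genotype")
    report = congruence.congruence_summary(harmonized)

    # neighborhood effect: restrict to individuals whose genotype and
    # morphology assignments agree on a pure label, then ask whether the
    # interfertility assignment matches that consensus
    consensus = harmonized[
        (harmonized["genotype"] == harmonized["morphology"])
        & harmonized["genotype"].isin(congruence.PURE)
    ]["genotype"]
    inter = harmonized["interfertility"].reindex(consensus.index)
    subset = inter.notna()
    congruent = (inter[subset] == consensus[subset]).astype(int)

    coords = stand.coords_frame().set_index("id")
    frac = congruence.allospecific_fraction(coords, consensus, radius=config.radius)
    neighborhood = None
    if congruent.nunique() == 2:
        neighborhood = congruence.congruence_glm(congruent, frac.reindex(congruent.index))
    return harmonized, report, neighborhood, congruent, frac


def run_pipeline(config: PipelineConfig, include_relatedness: bool = True, scan: bool = False) -> PipelineResult:
    """Run the full synthetic pipeline under one config and seed."""
    seeds = stage_seeds(config.seed)
    stand, offspring, refs = simulate_stage(config, seeds)
    paternity, mating_network = paternity_stage(config, stand, offspring)
    mating_scan, mating_fit = fit_stage(config, mating_network, seeds["fit_mating"], scan=scan)
    mating_labels = classify.classify_memberships(mating_fit, epsilon=config.epsilon, criterion="interfertility")

    relmatrix = calibration = rel_network = rel_fit = rel_labels = None
    if include_relatedness:
        relmatrix, calibration, rel_network = relatedness_stage(
            config, stand, offspring, paternity, mating_network, seeds["calibration"]
        )
        if rel_network.number_of_nodes() >= 3:
            rel_fit = csbm.fit_csbm(
                rel_network,
                Q=config.override_Q or 3,
                n_restarts=config.n_restarts,
                max_iter=config.max_iter,
                tol=config.tol,
                seed=seeds["fit_relatedness"],
            )
            rel_labels = classify.classify_memberships(rel_fit, epsilon=config.epsilon, criterion="relatedness")

    table, report, neighborhood, _, _ = congruence_stage(config, stand, mating_labels, refs, rel_labels)
    return PipelineResult(
        config=config,
        stand=stand,
        offspring=offspring,
        assignments_ref=refs,
        paternity=paternity,
        mating_network=mating_network,
        mating_scan=mating_scan,
        mating_fit=mating_fit,
        mating_labels=mating_labels,
        relmatrix=relmatrix,
        calibration=calibration,
        relatedness_network=rel_network,
        relatedness_fit=rel_fit,
        relatedness_labels=rel_labels,
        table=table,
        report=report,
        neighborhood=neighborhood,
    )
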