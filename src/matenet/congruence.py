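"""Congruence between species-delimitation criteria and the
neighborhood effect on incongruence.

Assignments from several criteria (interfertility, relatedness,
genotype, morphology) are compared after harmonizing their arbitrary
pure-group naming.  The summary counts fully consistent individuals,
species inversions (conflicting pure labels), and discrepancies
attributable to the intermediate class.  The neighborhood test asks
whether the proportion of allospecific neighbors within a radius (the
mean in-stand pollen dispersal distance) predicts incongruence between
the mating-derived assignment and the environment-independent
(genotype/morphology) consensus, via a logistic regression with a
likelihood-ratio test.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import chi2

import statsmodels.api as sm

logger = logging.getLogger("matenet.congruence")

PURE = ("S1", "S2")


@dataclasses.dataclass
class CongruenceReport:
    n: int
    n_complete: int
    consistent_counts: dict[str, int]  # pure label -> count fully consistent
    n_inversions: int
    n_intermediate_any: int
    n_discrepant: int
    frac_discrepancies_from_intermediates: float
    pairwise_agreement: pd.DataFrame


@dataclasses.dataclass
class NeighborhoodTest:
    slope: float
    intercept: float
    lr_chi2: float
    df: int
    p_value: float
    wald_chi2: float
    mean_fraction_congruent: float
    mean_fraction_incongruent: float
    n: int
    reliable: bool


def harmonize_labels(table: pd.DataFrame, reference: str | None = None) -> pd.DataFrame:
    """Align arbitrary pure-group names across criteria.

    For each non-reference criterion the S1/S2 naming is kept or swapped,
    whichever maximizes agreement with the reference criterion over
    individuals that are pure under both (an optimal 2x2 pairing, so the
    chosen mapping always agrees on at least half of the overlap).
    Intermediates are unaffected.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two criteria")
    reference = reference or table.columns[0]
    out = table.copy()
    ref = table[reference]
    for col in table.columns:
        if col == reference:
            continue
        mask = ref.isin(PURE) & table[col].isin(PURE)
        if not mask.any():
            raise ValueError(
                f"criterion {col!r} has no pure-label overlap with {reference!r}"
            )
        same = (ref[mask] == table.loc[mask, col]).sum()
        swapped = mask.sum() - same
        if swapped > same:
            out[col] = table[col].map({"S1": "S2", "S2": "S1"}).fillna(table[col])
    return out


def congruence_summary(table: pd.DataFrame) -> CongruenceReport:
    """Summarize agreement between harmonized assignment criteria.

    Over individuals with a label under every criterion: *fully
    consistent* rows carry the same pure label throughout; an *inversion*
    is a row with conflicting pure labels; every other incomplete
    agreement is a discrepancy, attributed to the intermediate class when
    no pure-label conflict is present.
    """
    complete = table.dropna()
    n_complete = len(complete)
    vals = complete.to_numpy()
    has_s1 = (vals == "S1").any(axis=1)
    has_s2 = (vals == "S2").any(axis=1)
    has_int = (vals == "intermediate").any(axis=1)
    all_same_pure = (~has_int) & (has_s1 ^ has_s2)
    inversions = has_s1 & has_s2
    discrepant = ~all_same_pure
    from_int = discrepant & ~inversions

    consistent_counts = {
        "S1": int((all_same_pure & has_s1).sum()),
        "S2": int((all_same_pure & has_s2).sum()),
    }
    n_disc = int(discrepant.sum())
    agreement = pd.DataFrame(
        np.eye(table.shape[1]), index=table.columns, columns=table.columns
    )
    for a, b in combinations(table.columns, 2):
        both = table[a].notna() & table[b].notna()
        frac = float((table.loc[both, a] == table.loc[both, b]).mean()) if both.any() else np.nan
        agreement.loc[a, b] = agreement.loc[b, a] = frac
    return CongruenceReport(
        n=len(table),
        n_complete=n_complete,
        consistent_counts=consistent_counts,
        n_inversions=int(inversions.sum()),
        n_intermediate_any=int(has_int.sum()),
        n_discrepant=n_disc,
        frac_discrepancies_from_intermediates=(
            float(from_int.sum() / n_disc) if n_disc else float("nan")
        ),
        pairwise_agreement=agreement,
    )


def allospecific_fraction(
    coords: pd.DataFrame,
    labels: pd.Series,
    radius: float,
) -> pd.Series:
    """Proportion of allospecific neighbors within ``radius`` meters.

    ``coords`` has columns x, y indexed by id; ``labels`` holds pure
    species labels (non-pure entries are ignored as both focals and
    neighbors).  Focals with zero neighbors are undefined (NaN).
    The fraction is evaluated against the focal's own label, so it is
    invariant to swapping S1 and S2.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    labels = labels[labels.isin(PURE)]
    ids = [i for i in labels.index if i in coords.index]
    xy = coords.loc[ids, ["x", "y"]].to_numpy(dtype=float)
    lab = labels.loc[ids].to_numpy()
    D = cdist(xy, xy)
    within = (D <= radius) & ~np.eye(len(ids), dtype=bool)
    total = within.sum(axis=1)
    allo = (within & (lab[None, :] != lab[:, None])).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, allo / np.maximum(total, 1), np.nan)
    return pd.Series(frac, index=pd.Index(ids, name="id"), name="allospecific_fraction")


def congruence_glm(congruent: pd.Series, fraction: pd.Series) -> NeighborhoodTest:
    """Logistic regression of assignment congruence on the allospecific
    neighbor fraction, with a likelihood-ratio test (df = 1).

    ``congruent`` is a binary indicator per individual; the slope is
    reported for the congruent outcome (a negative slope means congruent
    individuals have fewer allospecific neighbors).  Complete separation
    yields a flagged, unreliable result rather than an exception.
    """
    df = pd.DataFrame({"y": congruent, "x": fraction}).dropna()
    y = df["y"].astype(float).to_numpy()
    x = df["x"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("congruence outcome has a single class")
    mean_con = float(x[y == 1].mean())
    mean_inc = float(x[y == 0].mean())
    if np.ptp(x) == 0:
        return NeighborhoodTest(
            slope=0.0, intercept=float(sm.Logit(y, np.ones_like(y)).fit(disp=0).params[0]),
            lr_chi2=0.0, df=1, p_value=1.0, wald_chi2=0.0,
            mean_fraction_congruent=mean_con, mean_fraction_incongruent=mean_inc,
            n=len(y), reliable=True,
        )
    X = sm.add_constant(x)
    reliable = True
    try:
        with np.errstate(all="ignore"):
            full = sm.Logit(y, X).fit(disp=0, maxiter=200)
            null = sm.Logit(y, np.ones_like(y)).fit(disp=0, maxiter=200)
        params = np.asarray(full.params)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
            reliable = False
        lr = 2.0 * (full.llf - null.llf)
        slope = float(params[1])
        intercept = float(params[0])
        wald = float(full.tvalues[1] ** 2) if np.all(np.isfinite(full.bse)) else float("nan")
    except Exception:  # perfect separation or non-convergence
        logger.warning("logistic regression failed (likely complete separation)")
        reliable = False
        slope = float(np.sign(mean_con - mean_inc)) * np.inf
        intercept = float("nan")
        lr = float("nan")
        wald = float("nan")
    p = float(chi2.sf(lr, 1)) if np.isfinite(lr) else float("nan")
    return NeighborhoodTest(
        slope=slope,
        intercept=intercept,
        lr_chi2=float(lr),
        df=1,
        p_value=p,
        wald_chi2=wald,
        mean_fraction_congruent=mean_con,
        mean_fraction_incongruent=mean_inc,
        n=len(y),
        reliable=reliable,
    )
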