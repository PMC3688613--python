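"""Turn a three-EHN model fit into species assignments.

With Q = 3 the membership simplex is a triangle whose vertices are the
unconnected EHN 0 and the two species EHNs.  An individual is assigned
to a pure species when its node lies on the edge between EHN 0 and that
species' EHN, i.e. when its membership weight for the *other* species
EHN is at most ``epsilon``; all remaining nodes (true mixtures of both
species EHNs) are intermediates.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .csbm import CSBMFit

LABELS = ("S1", "S2", "intermediate")


def _species_columns(fit: CSBMFit) -> tuple[int, list[int]]:
    """Identify EHN 0 by its zero connectivity row; the other two EHNs
    are the species EHNs in canonical order."""
    if fit.Q != 3:
        raise ValueError(
            f"classification rule requires a 3-EHN fit (got Q={fit.Q}); "
            "refit with Q=3 or extend the rule"
        )
    zero_rows = [q for q in range(3) if np.all(np.abs(fit.B[q, :]) < 1e-12)]
    if not zero_rows:
        raise ValueError("no unconnected EHN found in the fit")
    q0 = zero_rows[0]
    species = [q for q in range(3) if q != q0]
    return q0, species


def classify_memberships(
    fit: CSBMFit,
    epsilon: float = 0.05,
    criterion: str = "interfertility",
) -> pd.DataFrame:
    """Assign each node to S1, S2 or intermediate.

    S1 if the weight on the second species EHN is <= ``epsilon``; S2 if
    the weight on the first is <= ``epsilon``; intermediate otherwise.
    Nodes whose weights on *both* species EHNs are <= ``epsilon`` sit at
    the EHN-0 vertex (almost no network information): they are labelled
    intermediate and flagged ``low_information``.
    """
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    q0, (q1, q2) = _species_columns(fit)
    w0, w1, w2 = fit.U[:, q0], fit.U[:, q1], fit.U[:, q2]
    low_info = (w1 <= epsilon) & (w2 <= epsilon)
    label = np.where(w2 <= epsilon, "S1", np.where(w1 <= epsilon, "S2", "intermediate"))
    label = np.where(low_info, "intermediate", label)
    return pd.DataFrame(
        {
            "label": label,
            "u0": w0,
            "u1": w1,
            "u2": w2,
            "low_information": low_info,
            "criterion": criterion,
        },
        index=pd.Index(fit.ids, name="id"),
    )


def ternary_coordinates(fit: CSBMFit) -> pd.DataFrame:
    """2-D barycentric embedding of the membership triangle.

    EHN 0 sits at the origin, the first species EHN at (1, 0) and the
    second at (0.5, sqrt(3)/2); a node's position is the weighted average
    of the vertices, so pure memberships map to vertices and the uniform
    mixture to the centroid.
    """
    q0, (q1, q2) = _species_columns(fit)
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]])
    W = fit.U[:, [q0, q1, q2]]
    xy = W @ verts
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}, index=pd.Index(fit.ids, name="id"))
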