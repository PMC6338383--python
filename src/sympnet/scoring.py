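"""Unweighted and centrality-weighted symptom scores.

The unweighted score is the plain symptom count.  Weighted variants multiply
each endorsed symptom by a node-level network metric (strength or the
Zhang–Horvath clustering coefficient) and sum, so symptoms that are more
central to the network contribute more.  Weights are used raw — only the
ordering of participants matters to the rank-based outcome statistics
downstream — and their provenance (group, metric, thresholded or not) is
recorded with the scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import CohortTable
from .symptoms import N_SYMPTOMS


def unweighted_score(profile) -> int:
    """Total number of endorsed symptoms (0-18)."""
    return int(np.asarray(profile).sum())


def weighted_score(profile, weights) -> float:
    """Sum of per-symptom weights over endorsed symptoms."""
    profile = np.asarray(profile, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != profile.shape:
        raise ValueError(
            f"weights shape {weights.shape} != profile shape {profile.shape}"
        )
    if not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite")
    return float(profile @ weights)


def score_cohort(
    cohort: CohortTable,
    centrality: pd.DataFrame,
    weights_group: str = "ADHD",
    thresholded: bool = False,
) -> pd.DataFrame:
    """Per-participant unweighted, strength-weighted and clustering-weighted
    scores.

    ``centrality`` is a table from :func:`sympnet.graph_metrics.centrality_table`
    with one row per symptom in canonical order.  The source of the weights
    is stored in ``DataFrame.attrs['weights_source']``.
    """
    if len(centrality) != N_SYMPTOMS:
        raise ValueError(
            f"centrality table must have {N_SYMPTOMS} rows, got {len(centrality)}"
        )
    profiles = cohort.profiles.astype(float)
    strength = centrality["strength"].to_numpy(dtype=float)
    clustering = centrality["clustering"].to_numpy(dtype=float)
    scores = pd.DataFrame(
        {
            "id": cohort.data["id"].to_numpy(),
            "group": cohort.data["group"].to_numpy(),
            "unweighted": profiles.sum(axis=1).astype(int),
            "strength_weighted": profiles @ strength,
            "clustering_weighted": profiles @ clustering,
        }
    )
    scores.attrs["weights_source"] = {
        "group": weights_group,
        "metrics": ("strength", "clustering"),
        "thresholded": thresholded,
    }
    return scores
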