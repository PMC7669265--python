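"""Validation metrics: matching detected objects against ground truth."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["match_centroids"]


def match_centroids(
    truth_um: np.ndarray, detected_um: np.ndarray, radius_um: float
) -> dict:
    """One-to-one match of detected centroids to true centroids within a radius.

    Uses optimal (Hungarian) assignment on the pairwise distance matrix with
    matches farther than ``radius_um`` disallowed.  Returns a dict with
    ``n_matched``, ``precision``, ``recall`` and ``mean_match_distance_um``.
    """
    truth_um = np.asarray(truth_um, float).reshape(-1, 3)
    detected_um = np.asarray(detected_um, float).reshape(-1, 3)
    nt, nd = len(truth_um), len(detected_um)
    if nt == 0 or nd == 0:
        return {
            "n_matched": 0,
            "precision": 0.0 if nd else np.nan,
            "recall": 0.0 if nt else np.nan,
            "mean_match_distance_um": np.nan,
        }
    dist = np.linalg.norm(truth_um[:, None, :] - detected_um[None, :, :], axis=2)
    big = radius_um * 1e6
    cost = np.where(dist <= radius_um, dist, big)
    rows, cols = linear_sum_assignment(cost)
    ok = dist[rows, cols] <= radius_um
    n_matched = int(ok.sum())
    return {
        "n_matched": n_matched,
        "precision": n_matched / nd,
        "recall": n_matched / nt,
        "mean_match_distance_um": float(dist[rows, cols][ok].mean()) if n_matched else np.nan,
    }
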