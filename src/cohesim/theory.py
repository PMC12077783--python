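"""Closed-form predictions for protrusion statistics and cluster speed.

An outermost agent proposes Gaussian displacements of standard deviation
``sigma``; outward proposals are unconstrained while inward ones are bounded
by the accessible gap ``delta`` to the constraining neighbor.  Modelling the
constrained side as a half-Gaussian truncated at ``delta`` gives the mean
inward reach, the net outward bias per protrusion event, and -- dividing the
per-event bias over the N cells sharing it and over the protrusion period T
-- a cluster-speed prediction.

These formulas describe the strong-gradient limit (leading cell relaxed back
to near contact before every event, trailing cell effectively free); the
simulator implements rejection rather than truncation, so the prediction is
an upper envelope: measured speeds can be slower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "AnalyticPrediction",
    "truncated_mean",
    "net_displacement",
    "predicted_speed",
    "predict",
    "prediction_table",
]

_HALF_NORMAL = np.sqrt(2.0 / np.pi)  # mean of |N(0, 1)|


def _check_sigma(sigma) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    return sigma


def truncated_mean(delta, sigma):
    """Mean reach of a half-Gaussian protrusion truncated at ``delta``.

    ``sqrt(2/pi) * sigma * (1 - exp(-delta^2 / 2 sigma^2)) / erf(delta / (sqrt(2) sigma))``,
    i.e. the mean of |N(0, sigma^2)| conditioned on not exceeding the
    accessible gap.  The ``delta -> 0`` limit is 0 (and ~ ``delta/2`` for
    ``delta << sigma``); the ``delta -> inf`` limit is the full half-normal
    mean ``sqrt(2/pi) * sigma``.
    """
    sigma = _check_sigma(sigma)
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("delta must be >= 0")
    u = delta / sigma
    small = u < 1e-8
    u_safe = np.where(small, 1.0, u)
    full = (
        _HALF_NORMAL
        * sigma
        * (1.0 - np.exp(-0.5 * u_safe**2))
        / special.erf(u_safe / np.sqrt(2.0))
    )
    out = np.where(small, 0.5 * delta, full)
    return out if out.ndim else float(out)


def net_displacement(delta, sigma):
    """Net outward bias per protrusion of a cell free on one side.

    The unconstrained mean minus the truncated mean:
    ``sqrt(2/pi)*sigma*[1 + (exp(-delta^2/2 sigma^2) - 1)/erf(delta/(sqrt(2) sigma))]``.
    Decreases from ``sqrt(2/pi)*sigma`` at ``delta << sigma`` to 0 at
    ``delta >> sigma``.
    """
    sigma = _check_sigma(sigma)
    out = _HALF_NORMAL * sigma - np.asarray(truncated_mean(delta, sigma))
    return out if out.ndim else float(out)


def predicted_speed(delta, sigma, n_cells, period):
    """Strong-gradient upper envelope of the cluster speed (radii/timestep).

    The leading cell's per-event bias ``net_displacement(delta, sigma)`` is
    shared by the N cells of the cluster once per protrusion period T:
    ``speed = net_displacement / (N * T)``.
    """
    n_cells = np.asarray(n_cells)
    period = np.asarray(period)
    if np.any(n_cells < 2):
        raise ValueError("n_cells must be >= 2")
    if np.any(period < 1):
        raise ValueError("period must be >= 1")
    out = np.asarray(net_displacement(delta, sigma)) / (n_cells * period)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AnalyticPrediction:
    """Bundle of the closed-form quantities for one (delta, sigma, N, T)."""

    delta: float
    sigma: float
    n_cells: int
    period: int
    mean_to_neighbor: float
    net_disp: float
    cluster_disp: float
    predicted_speed: float


def predict(delta, sigma, n_cells, period) -> AnalyticPrediction:
    """Evaluate all closed forms for one parameter point."""
    m = float(truncated_mean(delta, sigma))
    nd = float(net_displacement(delta, sigma))
    return AnalyticPrediction(
        delta=float(delta),
        sigma=float(sigma),
        n_cells=int(n_cells),
        period=int(period),
        mean_to_neighbor=m,
        net_disp=nd,
        cluster_disp=nd / n_cells,
        predicted_speed=nd / (n_cells * period),
    )


def prediction_table(deltas, sigmas, n_cells, period) -> pd.DataFrame:
    """Prediction grid for overlay against simulation sweeps."""
    rows = []
    for s in np.atleast_1d(sigmas):
        for d in np.atleast_1d(deltas):
            p = predict(d, s, n_cells, period)
            rows.append(
                {
                    "delta": p.delta,
                    "sigma": p.sigma,
                    "n_cells": p.n_cells,
                    "period": p.period,
                    "predicted_speed": p.predicted_speed,
                }
            )
    return pd.DataFrame(rows)
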