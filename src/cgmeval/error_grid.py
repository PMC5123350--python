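"""Clarke error-grid classification of paired glucose measurements.

The Clarke grid partitions the (reference, device) plane into five clinical
risk zones: A (clinically accurate: within 20% of the reference, or both
readings below 70 mg/dl), B (benign error), C (error prompting unnecessary
treatment), D (dangerous failure to detect hypo-/hyperglycemia) and E
(erroneous: hypoglycemia read as hyperglycemia or vice versa).  Each of
B-E splits into an upper (device reads high) and lower (device reads low)
sub-zone; A splits at the diagonal — ten sub-zones collapsing to the five
letters used for reporting.

Boundaries follow the classical 1987 piecewise-linear formulation with
inclusive comparisons, evaluated in the fixed order A, E, C, D, else B, which
makes the assignment exhaustive and unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

ZONES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class ErrorGridSummary:
    """Per-zone counts and percentages over the classified pairs.

    ``no_call`` carries the number of reference draws for which the device
    produced no reading (they are excluded from the classified n).
    """

    n: int
    counts: dict[str, int]
    percents: dict[str, float]
    no_call: int = 0

    @property
    def zone_ab_pct(self) -> float:
        return self.percents["A"] + self.percents["B"]


def _classify_arrays(ref: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Vectorized zone assignment; returns an array of 'A'..'E'."""
    if (ref <= 0).any() or (pred <= 0).any():
        raise ValueError("glucose values must be positive")
    if (ref >= 1000).any() or (pred >= 1000).any():
        raise ValueError("glucose values must be below 1000 mg/dl")

    zone = np.full(ref.shape, "B", dtype="<U1")

    a = ((ref <= 70) & (pred <= 70)) | ((pred >= 0.8 * ref) & (pred <= 1.2 * ref))
    e = ((ref >= 180) & (pred <= 70)) | ((ref <= 70) & (pred >= 180))
    c = ((ref >= 70) & (ref <= 290) & (pred >= ref + 110)) | (
        (ref >= 130) & (ref <= 180) & (pred <= (7.0 / 5.0) * ref - 182))
    d = ((ref >= 240) & (pred >= 70) & (pred <= 180)) | (
        (ref <= 175.0 / 3.0) & (pred >= 70) & (pred <= 180)) | (
        (ref >= 175.0 / 3.0) & (ref <= 70) & (pred >= (6.0 / 5.0) * ref))

    # precedence: A, then E, C, D, remainder B
    zone[d & ~(a | e | c)] = "D"
    zone[c & ~(a | e)] = "C"
    zone[e & ~a] = "E"
    zone[a] = "A"
    return zone


def classify_point(ref: float, pred: float) -> str:
    """Zone letter for a single (reference, device) pair in mg/dl."""
    z = _classify_arrays(np.asarray([float(ref)]), np.asarray([float(pred)]))
    return str(z[0])


def classify_subzone(ref: float, pred: float) -> str:
    """Ten-zone label: letter plus U (device high) or L (device low)."""
    zone = classify_point(ref, pred)
    return zone + ("U" if pred >= ref else "L")


class ClarkeErrorGrid(BaseEstimator):
    """Clarke-grid classifier over paired (reference, device) values.

    ``predict(X)`` with ``X`` of shape (n, 2) — columns reference then device,
    mg/dl — returns the zone letter per row.  ``fit`` is stateless and kept
    for pipeline compatibility.
    """

    def fit(self, X=None, y=None) -> "ClarkeErrorGrid":
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n, 2): [reference, device]")
        return _classify_arrays(X[:, 0], X[:, 1])


def summarize_zones(ref, pred, n_no_call: int = 0) -> ErrorGridSummary:
    """Zone counts/percentages over pooled pairs, with no-call bookkeeping."""
    ref = np.asarray(ref, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if ref.size == 0:
        raise ValueError("no pairs to classify")
    zones = _classify_arrays(ref, pred)
    counts = {z: int((zones == z).sum()) for z in ZONES}
    n = int(ref.size)
    percents = {z: 100.0 * counts[z] / n for z in ZONES}
    return ErrorGridSummary(n=n, counts=counts, percents=percents,
                            no_call=int(n_no_call))


def zone_points(ref, pred) -> list[tuple[float, float, str]]:
    """Plot-ready (reference, device, zone) triples for a grid rendering."""
    ref = np.asarray(ref, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    zones = _classify_arrays(ref, pred)
    return [(float(r), float(p), str(z)) for r, p, z in zip(ref, pred, zones)]


def plot_error_grid(ref, pred, ax=None):
    """Render a Clarke grid scatter (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pts = zone_points(ref, pred)
    colors = {"A": "tab:green", "B": "tab:olive", "C": "tab:orange",
              "D": "tab:red", "E": "tab:purple"}
    for z in ZONES:
        xs = [r for r, _, zz in pts if zz == z]
        ys = [p for _, p, zz in pts if zz == z]
        if xs:
            ax.scatter(xs, ys, s=8, c=colors[z], label=f"zone {z}")
    lim = max(400.0, max(max(r for r, _, _ in pts),
                         max(p for _, p, _ in pts)) * 1.05)
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("reference glucose (mg/dl)")
    ax.set_ylabel("device glucose (mg/dl)")
    ax.legend(loc="upper left", fontsize=8)
    return ax
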