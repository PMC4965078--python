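"""Constant-burst-size manifolds in the noise-versus-mean plane.

A population with burst size B sits on the hyperbola ``CV^2 = B / mean``
(count units) or ``CV^2 = 5000 (B + 1) / mean`` (MESF fluorescence
units): at fixed burst size, noise scales inversely with the mean, so a
burst-frequency change slides a clone *along* its manifold while a
burst-size change moves it *across* manifolds.  This module fits extreme
manifolds through the dimmest and brightest clones, measures the log-log
noise-versus-mean slope, and scores an activating perturbation for
noise contraction, manifold containment and frequency-versus-size
modulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .burst import MESF_PER_BURST, BurstEstimate
from .noise_stats import PopulationSummary

__all__ = [
    "ManifoldSet",
    "PerturbationResult",
    "manifold_cv2",
    "fit_extreme_manifolds",
    "loglog_slope",
    "perturbation_analysis",
]

_REL_EPS = 1e-9


def manifold_cv2(mean, burst_size: float, units: str = "fish"):
    """CV^2 on the constant-burst-size curve at the given mean.

    ``fish``: CV^2 = B / mean (molecule counts).
    ``mesf``: CV^2 = 5000 (B + 1) / mean (calibrated fluorescence).
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean must be > 0 on a manifold curve")
    if units == "fish":
        return burst_size / mean
    if units == "mesf":
        return MESF_PER_BURST * (burst_size + 1.0) / mean
    raise ValueError(f"units must be 'fish' or 'mesf', got {units!r}")


@dataclass(frozen=True)
class ManifoldSet:
    """An ordered family of constant-burst-size curves in one unit system."""

    burst_levels: tuple[float, ...]
    units: str = "fish"

    def __post_init__(self):
        if self.units not in ("fish", "mesf"):
            raise ValueError("units must be 'fish' or 'mesf'")
        if any(b < 0 for b in self.burst_levels):
            raise ValueError("burst levels must be >= 0")
        if list(self.burst_levels) != sorted(self.burst_levels):
            raise ValueError("burst levels must be ordered")

    @classmethod
    def integer_grid(cls, grid_max: int = 12, units: str = "fish") -> "ManifoldSet":
        return cls(tuple(float(b) for b in range(grid_max + 1)), units=units)

    def cv2(self, mean, burst_size: float):
        return manifold_cv2(mean, burst_size, units=self.units)

    def curve_table(self, mean_grid) -> pd.DataFrame:
        """Plotting-ready long table of (B, mean, cv2) for every level."""
        mean_grid = np.asarray(mean_grid, dtype=float)
        frames = []
        for b in self.burst_levels:
            frames.append(
                pd.DataFrame({"B": b, "mean_grid": mean_grid, "cv2": self.cv2(mean_grid, b)})
            )
        return pd.concat(frames, ignore_index=True)


def fit_extreme_manifolds(estimates: list[BurstEstimate]) -> tuple[float, float]:
    """(B_min, B_max): manifolds through the dimmest and brightest clones.

    Each extreme manifold is the one-parameter hyperbola passing exactly
    through one clone's (mean, CV^2) point: B_min through the clone with
    the smallest mean, B_max through the clone with the largest.  On
    panels where burst size grows with expression these two curves
    bracket the whole panel.
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 clones to fit extreme manifolds")
    dimmest = min(estimates, key=lambda e: e.mean)
    brightest = max(estimates, key=lambda e: e.mean)
    return dimmest.burst_size, brightest.burst_size


def loglog_slope(summaries: list[PopulationSummary]) -> tuple[float, float, float]:
    """Least-squares slope of log CV^2 against log mean.

    Returns ``(slope, intercept, r)`` with natural logs; populations
    sliding along a single exact manifold B give slope -1 and intercept
    log B.  Requires at least three populations with positive means and a
    non-degenerate spread of means.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 populations for a slope fit")
    means = np.array([s.mean for s in summaries], dtype=float)
    cv2s = np.array([s.cv2 for s in summaries], dtype=float)
    if np.any(means <= 0) or np.any(cv2s <= 0):
        raise ValueError("all means and CV^2 must be > 0 for a log-log fit")
    x = np.log(means)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate mean range: log-log slope undefined")
    fit = stats.linregress(x, np.log(cv2s))
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


@dataclass(frozen=True)
class PerturbationResult:
    """Paired before/after scoring of an activating perturbation.

    ``contraction_fraction`` — clones whose mean rose while CV^2 fell
    (noise contracting down the manifold); ``containment_fraction`` —
    share of all points lying between the extreme manifolds;
    ``modulation_class`` — per-clone verdict: ``frequency`` when burst
    size is unchanged within the relative threshold, ``size`` when it
    changed with the mean rising, ``mixed`` otherwise.
    """

    clones: tuple[str, ...]
    b_min: float
    b_max: float
    contraction_fraction: float
    containment_fraction: float
    n_above_exclusion: int
    n_below_exclusion: int
    modulation_class: dict = field(default_factory=dict)
    per_clone: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clones"] = list(self.clones)
        d["per_clone"] = None if self.per_clone is None else self.per_clone.to_dict("records")
        return d


def perturbation_analysis(
    before: list[BurstEstimate],
    after: list[BurstEstimate],
    manifolds: tuple[float, float] | None = None,
    rel_threshold: float = 0.25,
    exclusion_margin: float = 1.5,
    containment_tol: float = 0.15,
) -> PerturbationResult:
    """Score a matched baseline/perturbed pair of burst-estimate panels.

    ``manifolds`` is the (B_min, B_max) pair to test containment against;
    by default they are fitted to the *before* panel, mirroring the
    convention of fitting extreme manifolds to the unperturbed clones.
    Containment counts both conditions' points whose burst size lies in
    the band [B_min (1 - tol), B_max (1 + tol)] with
    ``tol = containment_tol``.  The band carries finite width because the
    constant-burst-size curves are the bursting-limit idealization: at
    finite promoter switching rates the Fano factor drifts by order 10%
    across the burst-frequency range of a panel, and moment estimates at
    a few thousand cells fluctuate comparably, so points slide slightly
    off the curves they are constrained to.  The exclusion counts report
    points beyond the extreme manifolds by more than
    ``exclusion_margin`` — the upper-right and lower-left regions of the
    noise-mean plane that the burst-size constraint leaves devoid of
    data.
    """
    bmap = {e.clone_id: e for e in before}
    amap = {e.clone_id: e for e in after}
    missing = sorted(set(bmap) ^ set(amap))
    if missing:
        raise ValueError(f"clones not matched across conditions: {missing}")
    if manifolds is None:
        manifolds = fit_extreme_manifolds(before)
    b_min, b_max = manifolds
    if b_min > b_max:
        b_min, b_max = b_max, b_min

    clones = tuple(sorted(bmap))
    rows = []
    n_contract = 0
    for c in clones:
        eb, ea = bmap[c], amap[c]
        mean_up = ea.mean > eb.mean
        cv2_down = ea.cv2 < eb.cv2
        if mean_up and cv2_down:
            n_contract += 1
        rel_db = abs(ea.burst_size - eb.burst_size) / eb.burst_size if eb.burst_size > 0 else np.inf
        if rel_db <= rel_threshold:
            cls = "frequency"
        elif mean_up:
            cls = "size"
        else:
            cls = "mixed"
        rows.append(
            {
                "clone_id": c,
                "mean_before": eb.mean,
                "mean_after": ea.mean,
                "cv2_before": eb.cv2,
                "cv2_after": ea.cv2,
                "burst_size_before": eb.burst_size,
                "burst_size_after": ea.burst_size,
                "rel_delta_burst_size": rel_db,
                "modulation_class": cls,
            }
        )
    per_clone = pd.DataFrame(rows)

    all_b = np.array([e.burst_size for e in before + after])
    lo = b_min * (1.0 - containment_tol - _REL_EPS)
    hi = b_max * (1.0 + containment_tol + _REL_EPS)
    contained = (all_b >= lo) & (all_b <= hi)
    above = int(np.sum(all_b > b_max * exclusion_margin))
    below = int(np.sum(all_b < b_min / exclusion_margin))

    return PerturbationResult(
        clones=clones,
        b_min=float(b_min),
        b_max=float(b_max),
        contraction_fraction=n_contract / len(clones),
        containment_fraction=float(contained.mean()),
        n_above_exclusion=above,
        n_below_exclusion=below,
        modulation_class={r["clone_id"]: r["modulation_class"] for r in rows},
        per_clone=per_clone,
    )
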