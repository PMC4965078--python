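"""Two-state (random telegraph) model of stochastic gene expression.

The promoter toggles OFF -> ON at rate ``k_on`` and ON -> OFF at rate
``k_off``; while ON it transcribes mRNA at rate ``T``.  mRNA decays at
``d_m`` per molecule, is translated at ``L`` per molecule, and protein
decays at ``d_p``.  In the bursting regime (``k_off >> k_on``) the model
produces geometric bursts of mean size ``b = T / k_off`` at frequency
``k_on``, and the squared coefficient of variation of protein abundance
falls on a hyperbola in the noise-versus-mean plane:

    CV^2 = C * (1 + T/k_off) / <protein>,   C = L / (d_m + d_p)

All rates are dimensionless, expressed per mRNA lifetime (``d_m = 1`` is
the conventional choice); the data this package targets carry no absolute
time units, only rate ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TelegraphParams",
    "analytic_protein_cv2",
    "analytic_mrna_moments",
    "analytic_protein_moments",
    "sample_mrna_exact",
]


@dataclass(frozen=True)
class TelegraphParams:
    """Kinetic rates of the two-state promoter model.

    Parameters
    ----------
    k_on : float
        Promoter OFF -> ON rate (burst-frequency parameter).
    k_off : float
        Promoter ON -> OFF rate.  ``T / k_off`` is the mean burst size.
    T : float
        Transcription rate while the promoter is ON.
    L : float
        Translation rate per mRNA molecule.
    d_m : float
        mRNA degradation rate per molecule.
    d_p : float
        Protein degradation rate per molecule.
    """

    k_on: float
    k_off: float
    T: float
    L: float = 0.0
    d_m: float = 1.0
    d_p: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "T", "L", "d_m", "d_p"):
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v!r}")
        if self.T > 0 and self.d_m <= 0:
            raise ValueError("d_m must be > 0 when T > 0 (stationarity requires mRNA decay)")

    @property
    def burst_size(self) -> float:
        """Mean mRNA per ON period, b = T / k_off (requires k_off > 0)."""
        if self.k_off <= 0:
            raise ValueError("burst size T/k_off is undefined for k_off = 0")
        return self.T / self.k_off

    # -- JSON round-trip (keys are the canonical rate names) ----------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TelegraphParams":
        return cls(**{k: float(d[k]) for k in ("k_on", "k_off", "T", "L", "d_m", "d_p") if k in d})

    def replace(self, **kw) -> "TelegraphParams":
        d = self.to_dict()
        d.update(kw)
        return TelegraphParams(**d)


def analytic_protein_cv2(params: TelegraphParams, mean_protein: float) -> float:
    """Protein noise CV^2 on the constant-burst-size hyperbola.

    Evaluates ``CV^2 = C (1 + T/k_off) / mean_protein`` with
    ``C = L / (d_m + d_p)``.  This is the bursting-regime closed form: at
    fixed burst size the noise scales inversely with the mean, so a
    promoter whose burst frequency is modulated slides along this curve.
    """
    if mean_protein <= 0:
        raise ValueError(f"mean_protein must be > 0, got {mean_protein!r}")
    if params.k_off <= 0:
        raise ValueError("k_off must be > 0: burst size T/k_off is undefined")
    denom = params.d_m + params.d_p
    if denom <= 0:
        raise ValueError("d_m + d_p must be > 0")
    c = params.L / denom
    return c * (1.0 + params.T / params.k_off) / mean_protein


def analytic_mrna_moments(params: TelegraphParams) -> tuple[float, float]:
    """Exact stationary mean and Fano factor of the mRNA copy number.

    Returns
    -------
    (mean, fano) : tuple of float
        ``mean = T k_on / (d_m (k_on + k_off))`` and
        ``fano = 1 + T k_off / ((k_on + k_off)(k_on + k_off + d_m))``.
        When the mean is zero the Fano factor is undefined and returned
        as NaN.

    Notes
    -----
    In the bursting limit (``k_off, T -> inf`` at fixed ``b = T/k_off``)
    the Fano factor tends to ``1 + b``: the Fano factor is the operational
    burst-size readout of count data.
    """
    if params.d_m <= 0:
        raise ValueError("d_m must be > 0 for a stationary mRNA distribution")
    ksum = params.k_on + params.k_off
    if ksum == 0 or params.k_on == 0 or params.T == 0:
        # promoter frozen OFF or silent: degenerate at zero copies
        mean = 0.0 if (params.k_on == 0 or params.T == 0) else params.T / params.d_m
        return mean, float("nan") if mean == 0 else 1.0
    mean = params.T * params.k_on / (params.d_m * ksum)
    fano = 1.0 + params.T * params.k_off / (ksum * (ksum + params.d_m))
    return mean, fano


def analytic_protein_moments(params: TelegraphParams) -> tuple[float, float]:
    """Bursting-regime stationary protein mean and CV^2.

    Mean is exact, ``<p> = <m> L / d_p``; CV^2 comes from the
    constant-burst-size hyperbola (see :func:`analytic_protein_cv2`),
    which is accurate when translation amplifies transcriptional bursts
    (``L / (d_m + d_p) >> 1``) and the promoter is bursty
    (``k_off >> k_on``).
    """
    if params.d_p <= 0 or params.L <= 0:
        raise ValueError("protein moments require L > 0 and d_p > 0")
    mean_m, _ = analytic_mrna_moments(params)
    if mean_m <= 0:
        raise ValueError("mRNA mean is zero; protein CV^2 undefined")
    mean_p = mean_m * params.L / params.d_p
    return mean_p, analytic_protein_cv2(params, mean_p)


def sample_mrna_exact(params: TelegraphParams, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Draw stationary mRNA copy numbers from the exact Poisson-beta law.

    The stationary mRNA distribution of the telegraph model is a Poisson
    mixture over a beta-distributed promoter activity:
    ``m ~ Poisson((T/d_m) q)`` with ``q ~ Beta(k_on/d_m, k_off/d_m)``.
    This draws i.i.d. stationary counts without simulating trajectories;
    the SSA (:func:`burstnoise.ssa.sample_steady_state`) provides the
    dynamically exact cross-check.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if params.d_m <= 0:
        raise ValueError("d_m must be > 0")
    a = params.k_on / params.d_m
    b = params.k_off / params.d_m
    if a == 0:
        return np.zeros(n_cells, dtype=np.int64)
    if b == 0:
        # promoter permanently ON at stationarity: Poisson(T/d_m)
        q = np.ones(n_cells)
    else:
        q = rng.beta(a, b, size=n_cells)
    return rng.poisson(params.T / params.d_m * q).astype(np.int64)
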