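"""Exact stochastic simulation (Gillespie SSA) of the telegraph model.

Reactions: OFF->ON at ``k_on``; ON->OFF at ``k_off``; mRNA birth at ``T``
while ON; mRNA death at ``d_m * m``; protein birth at ``L * m``; protein
death at ``d_p * p``.

Two entry points:

* :func:`simulate_ssa` — a single full trajectory (pure Python; meant for
  inspection and small tests).
* :func:`sample_steady_state` — independent end-of-burn-in states for many
  cells (numba-compiled hot loop; this is what population statistics use).

Reproducibility contract: identical ``(params, seed, n)`` give identical
output.  Per-cell streams are derived from the master seed with
``numpy.random.SeedSequence``, so cell i's draw does not depend on how many
cells are requested before it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .telegraph import TelegraphParams

__all__ = ["Trajectory", "simulate_ssa", "sample_steady_state", "default_burnin"]


@dataclass
class Trajectory:
    """Piecewise-constant sample path.

    ``times[i]`` is the time at which the i-th recorded state begins
    (``times[0] == 0``); the state holds until ``times[i+1]`` (or ``t_end``).
    """

    times: np.ndarray
    promoter_state: np.ndarray
    mrna_count: np.ndarray
    protein_count: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.mrna_count < 0) or np.any(self.protein_count < 0):
            raise ValueError("molecule counts must be non-negative")


def _check_reactive(p: TelegraphParams, record_protein: bool) -> None:
    rates = [p.k_on, p.k_off, p.T, p.d_m]
    if record_protein:
        rates += [p.L, p.d_p]
    if all(r == 0 for r in rates):
        raise ValueError("all rates are zero: no reaction can ever fire")


def simulate_ssa(
    params: TelegraphParams,
    t_end: float,
    seed: int,
    record_protein: bool = False,
) -> Trajectory:
    """Run one exact Gillespie realization from (OFF, 0 mRNA, 0 protein).

    When ``record_protein`` is False the translation/protein-decay channels
    are switched off entirely, which keeps mRNA-level analyses cheap.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    _check_reactive(params, record_protein)
    rng = np.random.default_rng(seed)
    k_on, k_off, T, d_m = params.k_on, params.k_off, params.T, params.d_m
    L = params.L if record_protein else 0.0
    d_p = params.d_p if record_protein else 0.0

    t, g, m, p = 0.0, 0, 0, 0
    times, gs, ms, ps = [0.0], [0], [0], [0]
    while True:
        a = (
            k_on if g == 0 else k_off,
            T if g == 1 else 0.0,
            d_m * m,
            L * m,
            d_p * p,
        )
        a_tot = sum(a)
        if a_tot <= 0.0:
            break  # absorbing state; holds until t_end
        t += rng.exponential(1.0 / a_tot)
        if t >= t_end:
            break
        r = rng.random() * a_tot
        if r < a[0]:
            g = 1 - g
        elif r < a[0] + a[1]:
            m += 1
        elif r < a[0] + a[1] + a[2]:
            m -= 1
        elif r < a[0] + a[1] + a[2] + a[3]:
            p += 1
        else:
            p -= 1
        times.append(t)
        gs.append(g)
        ms.append(m)
        ps.append(p)
    return Trajectory(
        times=np.asarray(times),
        promoter_state=np.asarray(gs, dtype=np.int64),
        mrna_count=np.asarray(ms, dtype=np.int64),
        protein_count=np.asarray(ps, dtype=np.int64),
    )


@njit
def _ssa_final(k_on, k_off, T, L, d_m, d_p, t_end, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    t = 0.0
    g = 0
    m = 0
    p = 0
    while True:
        a0 = k_on if g == 0 else k_off
        a1 = T if g == 1 else 0.0
        a2 = d_m * m
        a3 = L * m
        a4 = d_p * p
        a_tot = a0 + a1 + a2 + a3 + a4
        if a_tot <= 0.0:
            break
        t += np.random.exponential(1.0 / a_tot)
        if t >= t_end:
            break
        r = np.random.random() * a_tot
        if r < a0:
            g = 1 - g
        elif r < a0 + a1:
            m += 1
        elif r < a0 + a1 + a2:
            m -= 1
        elif r < a0 + a1 + a2 + a3:
            p += 1
        else:
            p -= 1
    return m, p


def default_burnin(params: TelegraphParams, record_protein: bool, multiplier: float = 10.0) -> float:
    """Burn-in long enough to forget the empty initial condition.

    ``multiplier`` times the slowest relaxation timescale among
    ``1/d_m``, ``1/d_p`` (protein runs only) and ``1/(k_on + k_off)``.
    """
    scales = []
    if params.d_m > 0:
        scales.append(1.0 / params.d_m)
    if record_protein and params.d_p > 0:
        scales.append(1.0 / params.d_p)
    if params.k_on + params.k_off > 0:
        scales.append(1.0 / (params.k_on + params.k_off))
    if not scales:
        raise ValueError("no finite relaxation timescale; cannot choose a burn-in")
    return multiplier * max(scales)


def sample_steady_state(
    params: TelegraphParams,
    n_cells: int,
    seed: int,
    record_protein: bool = False,
    burnin_multiplier: float = 10.0,
) -> np.ndarray:
    """Independent stationary (mRNA, protein) draws for ``n_cells`` cells.

    Each cell is an independent SSA run of length ``default_burnin`` from
    the empty state; the end state is recorded.  Returns an array of shape
    ``(n_cells, 2)`` with columns (mrna_count, protein_count); the protein
    column is zero unless ``record_protein``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    _check_reactive(params, record_protein)
    if record_protein and (params.L <= 0 or params.d_p <= 0):
        raise ValueError("record_protein requires L > 0 and d_p > 0")
    t_end = default_burnin(params, record_protein, burnin_multiplier)
    L = params.L if record_protein else 0.0
    d_p = params.d_p if record_protein else 0.0
    cell_seeds = np.random.SeedSequence(seed).generate_state(n_cells, dtype=np.uint32)
    out = np.empty((n_cells, 2), dtype=np.int64)
    for i in range(n_cells):
        out[i] = _ssa_final(
            params.k_on, params.k_off, params.T, L, params.d_m, d_p, t_end, cell_seeds[i]
        )
    return out
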