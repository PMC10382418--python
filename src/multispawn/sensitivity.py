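"""One-at-a-time parameter sensitivity analysis of spawning dynamics.

Each parameter is varied individually around the reference settings while
all others stay fixed; every variant runs the full ensemble from the *same*
initial conditions (strict pairing), so any deviation in the excited-state
population trace is attributable to the parameter alone.  The per-time-step
signed relative deviations from the reference trace are pooled (optionally
dropping the most extreme value tested) and summarized by a Gaussian kernel
density estimate with Scott's bandwidth — the estimated probability
distribution function (EPDF) of the deviation.  An L1 deviation of the
time-dependent nuclear density against the grid reference provides the
complementary, basis-set-independent measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gaussian_kde

from .amplitudes import SimParams
from .driver import EnsembleResult, PopulationTrace, run_ensemble, wigner_sample
from .models import LVCModel

__all__ = [
    "SweepResult",
    "signed_relative_deviation",
    "scott_factor",
    "kde_scott",
    "density_deviation",
    "sweep",
    "SWEEPABLE",
]

#: Parameters accepted by :func:`sweep`.
SWEEPABLE = (
    "timestep", "csthresh", "poptospawn", "omax",
    "olapthresh", "regthresh", "widths",
)


def signed_relative_deviation(
    trace: PopulationTrace,
    ref_trace: PopulationTrace,
    floor: float = 0.01,
    state: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(P(t) - P_ref(t)) / P_ref(t) for the tracked state on the common grid.

    Times where the reference population falls below ``floor`` are dropped
    (the ratio is dominated by noise there); the returned arrays are the
    retained times and the deviations.
    """
    if trace.times.shape != ref_trace.times.shape or not np.allclose(
        trace.times, ref_trace.times
    ):
        raise ValueError("traces must share a common time grid")
    if state is None:
        state = trace.populations.shape[1] - 1
    p = trace.populations[:, state]
    pr = ref_trace.populations[:, state]
    keep = pr >= floor
    return trace.times[keep], (p[keep] - pr[keep]) / pr[keep]


def scott_factor(n: int, d: int = 1) -> float:
    """Scott's bandwidth factor n**(-1/(d+4)); n**(-1/5) in one dimension."""
    return float(n) ** (-1.0 / (d + 4))


def kde_scott(
    samples, grid: np.ndarray | None = None, n_grid: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density estimate with Scott's bandwidth.

    Bandwidth = sample standard deviation x n**(-1/5).  Returns the
    evaluation grid and the density, which integrates to ~1 on a grid wide
    enough to hold the distribution (the default spans the sample range
    plus four bandwidths on each side).
    """
    x = np.asarray(samples, float).ravel()
    if x.size < 2:
        raise ValueError("at least two samples are required")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("samples have zero spread; the KDE is degenerate")
    kde = gaussian_kde(x, bw_method="scott")  # factor n**(-1/5) in 1-D
    if grid is None:
        h = sd * scott_factor(x.size)
        lo, hi = x.min() - 4 * h, x.max() + 4 * h
        grid = np.linspace(lo, hi, n_grid)
    return grid, kde(grid)


def density_deviation(
    densities, ref_densities, grid
) -> np.ndarray:
    """Integrated absolute nuclear-density deviation per output time:
    ``int |rho(t) - rho_ref(t)| dq`` (Riemann sum).

    ``grid`` may be a :class:`~multispawn.qd.Grid` or a volume element.
    Bounded by 2 for two unit-norm densities.
    """
    dV = getattr(grid, "dV", grid)
    a = np.asarray(densities, float)
    b = np.asarray(ref_densities, float)
    if a.shape != b.shape:
        raise ValueError("density series must share shape and grid")
    axes = tuple(range(1, a.ndim))
    return np.abs(a - b).sum(axis=axes) * float(dV)


@dataclass
class SweepResult:
    """Outcome of a one-parameter sweep with shared initial conditions."""

    parameter: str
    values: list
    reference: PopulationTrace
    traces: dict = field(default_factory=dict)      # value -> averaged trace
    deviations: dict = field(default_factory=dict)  # value -> (times, devs)
    pooled: np.ndarray = None                        # type: ignore[assignment]
    epdf_grid: np.ndarray = None                     # type: ignore[assignment]
    epdf: np.ndarray = None                          # type: ignore[assignment]
    excluded_value: object = None
    ensembles: dict = field(default_factory=dict)


def _base_value(params: SimParams, name: str):
    if name == "widths":
        return 1.0  # widths sweeps are multiplicative factors on the baseline
    return getattr(params, name)


def _extremeness(value, base) -> float:
    v, b = float(value), float(base)
    if v > 0 and b > 0:
        return abs(np.log(v / b))
    return abs(v - b)


def sweep(
    param_name: str,
    values,
    base_params: SimParams,
    model: LVCModel,
    n_ic: int | None = None,
    seed: int | None = None,
    exclude_extreme: bool = True,
    floor: float = 0.01,
    state: int | None = None,
    reference: EnsembleResult | None = None,
    progress: bool = False,
) -> SweepResult:
    """Run the ensemble for every value of one parameter and summarize.

    All runs (including the reference) share the same Wigner-sampled initial
    conditions, so a value equal to the reference reproduces the reference
    trace exactly.  Deviations are pooled over time steps and values
    (optionally excluding the most extreme value tested) before the KDE.
    """
    if param_name not in SWEEPABLE:
        raise ValueError(
            f"unknown parameter {param_name!r}; choose from {SWEEPABLE}"
        )
    params = base_params
    if n_ic is not None:
        params = replace(params, n_ic=n_ic)
    if seed is not None:
        params = replace(params, seed=seed)
    ics = wigner_sample(model, params.n_ic, params.seed)
    if state is None:
        state = (model.n_states - 1 if params.initial_state is None
                 else params.initial_state)

    if reference is None:
        reference = run_ensemble(model, params, ics=ics, progress=progress)
    result = SweepResult(parameter=param_name, values=list(values),
                         reference=reference.average)
    base = _base_value(params, param_name)
    for value in values:
        if progress:  # pragma: no cover
            print(f"sweep {param_name} = {value}")
        variant = replace(params, **{param_name: value})
        ens = run_ensemble(model, variant, ics=ics, progress=progress)
        result.ensembles[value] = ens
        result.traces[value] = ens.average
        result.deviations[value] = signed_relative_deviation(
            ens.average, reference.average, floor=floor, state=state
        )

    pool_values = list(values)
    if exclude_extreme and len(pool_values) > 1:
        result.excluded_value = max(
            pool_values, key=lambda v: _extremeness(v, base)
        )
        pool_values.remove(result.excluded_value)
    pooled = [result.deviations[v][1] for v in pool_values]
    result.pooled = (np.concatenate(pooled) if pooled
                     else np.empty(0))
    if result.pooled.size >= 2 and result.pooled.std(ddof=1) > 0:
        result.epdf_grid, result.epdf = kde_scott(result.pooled)
    return result
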