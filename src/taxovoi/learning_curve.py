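"""Von Bertalanffy learning curves and the value of information (VoI).

Model performance as a function of training-set size is modelled with the
Von Bertalanffy Growth Function (VBGF)

    L(t) = L_inf * (1 - exp(-k * (t - t0)))

where L is the (average) F1 score, t the number of training observations
per species, L_inf the asymptotic maximum F1, k the growth rate and t0 the
hypothetical size at which F1 would be zero.  Its derivative

    dL/dt = b * k * exp(-k * t),    b = L_inf * exp(k * t0)

is the marginal performance gain of one more training observation per
species.  Evaluating the slope at a taxon's current average data
availability t_avg = (observations with images) / (accepted species) and
dividing by the number of accepted species gives the VoI of adding a
single observation with images to that taxon: the expected F1 increase it
buys, accounting for how far along its learning curve the taxon already is
and across how many species the new observation's benefit is diluted.

Fitting is deterministic nonlinear least squares on the mean F1 per task
size (trust-region reflective, analytic-free residuals, fixed data-driven
initialization with a small fallback multistart on the growth rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_eval import PerformancePoint
from .taxonomy_bias import RepresentationResult

#: parameter bounds: L_inf may exceed 1 slightly to avoid boundary bias
L_INF_MAX = 1.2
K_BOUNDS = (1e-6, 10.0)


@dataclass(frozen=True)
class VBGFParams:
    """VBGF parameters (L_inf, k, t0) with the derived coefficient b."""

    l_inf: float
    k: float
    t0: float

    @property
    def b(self) -> float:
        return self.l_inf * math.exp(self.k * self.t0)


@dataclass(frozen=True)
class CurveFit:
    taxon: str
    params: VBGFParams
    n_points: int        # distinct task sizes entering the fit
    rss: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class VoIEstimate:
    taxon: str
    t_avg: float         # average image-bearing observations per species
    n_species: int       # accepted species in the taxon
    slope_at_t: float    # dL/dt at t_avg, F1 per observation-per-species
    voi: float           # slope_at_t / n_species, F1 per added observation


def vbgf(t, params: VBGFParams):
    """Evaluate L(t) = L_inf * (1 - exp(-k (t - t0))); vectorized in t."""
    return params.l_inf * (1.0 - np.exp(-params.k * (np.asarray(t,
                           dtype=float) - params.t0)))


def vbgf_slope(t, params: VBGFParams):
    """Evaluate dL/dt = b k exp(-k t); strictly decreasing in t for k>0."""
    return params.b * params.k * np.exp(-params.k * np.asarray(t,
                                        dtype=float))


def _mean_by_size(points: Iterable[PerformancePoint],
                  ) -> tuple[np.ndarray, np.ndarray]:
    acc: dict[int, list[float]] = {}
    for p in points:
        acc.setdefault(p.size, []).append(p.f1)
    sizes = np.array(sorted(acc), dtype=float)
    means = np.array([np.mean(acc[int(s)]) for s in sizes])
    return sizes, means


def _initial_guess(t: np.ndarray, f1: np.ndarray) -> np.ndarray:
    l0 = min(float(f1.max()), 1.0)
    # log-linear regression of log(L_inf - F1) on t estimates -k
    diff = np.maximum(l0 * 1.001 - f1, 1e-6)
    slope = np.polyfit(t, np.log(diff), 1)[0]
    k0 = float(np.clip(-slope, 1e-4, 1.0))
    return np.array([max(l0, 1e-3), k0, 0.0])


def fit_vbgf(points: Sequence[PerformancePoint],
             taxon: str | None = None,
             use_means: bool = True) -> CurveFit:
    """Least-squares VBGF fit to F1-vs-size points for one taxon.

    The fit target is the mean F1 per task size (``use_means``, default);
    fitting every replicate point directly gives the same optimum when
    replicates are balanced across sizes.  Requires at least 3 distinct
    sizes.  Deterministic: fixed initialization, no randomness; if the
    primary start does not converge, a small fixed grid of growth rates is
    tried and the best solution kept.

    A degenerate input (constant F1 at every size) is flagged as
    non-converged: k is unidentifiable there.
    """
    if taxon is None:
        taxa = {p.taxon for p in points}
        taxon = taxa.pop() if len(taxa) == 1 else "+".join(sorted(taxa))
    sizes, means = _mean_by_size(points)
    if len(sizes) < 3:
        raise ValueError(
            f"need >= 3 distinct task sizes to fit, got {len(sizes)}")
    if use_means:
        t, y = sizes, means
    else:
        t = np.array([p.size for p in points], dtype=float)
        y = np.array([p.f1 for p in points], dtype=float)

    degenerate = float(np.ptp(means)) < 1e-12

    def resid(x):
        return vbgf(t, VBGFParams(*x)) - y

    lower = [1e-6, K_BOUNDS[0], -10.0 * float(t.max())]
    upper = [L_INF_MAX, K_BOUNDS[1], float(t.min())]

    def solve(x0):
        x0 = np.clip(x0, lower, upper)
        return least_squares(resid, x0, bounds=(lower, upper),
                             method="trf", xtol=1e-12, ftol=1e-12,
                             gtol=1e-12)

    res = solve(_initial_guess(t, y))
    if not res.success:
        for k0 in (0.005, 0.02, 0.1):
            alt = solve([min(float(y.max()) + 0.05, 1.0), k0, 0.0])
            if alt.cost < res.cost:
                res = alt
    params = VBGFParams(*(float(v) for v in res.x))
    rss = float(2.0 * res.cost)
    converged = bool(res.success) and not degenerate
    message = "degenerate: constant F1, k unidentifiable" if degenerate \
        else res.message
    return CurveFit(taxon=taxon, params=params, n_points=len(sizes),
                    rss=rss, converged=converged, message=message)


def voi_estimate(fit: CurveFit, n_obs_images: int,
                 n_species: int) -> VoIEstimate:
    """VoI of one additional image-bearing observation for a taxon.

    ``t_avg = n_obs_images / n_species`` is substituted into the fitted
    curve's slope, and the result divided by ``n_species``.
    """
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    if n_obs_images < 0:
        raise ValueError("n_obs_images must be non-negative")
    t_avg = n_obs_images / n_species
    slope = float(vbgf_slope(t_avg, fit.params))
    return VoIEstimate(taxon=fit.taxon, t_avg=t_avg, n_species=n_species,
                       slope_at_t=slope, voi=slope / n_species)


def voi_bias_table(vois: Sequence[VoIEstimate],
                   bias: Sequence[RepresentationResult]) -> pd.DataFrame:
    """Join per-taxon VoI estimates with relative-representation results.

    One row per taxon with n_x, s_x, R_x (raw and asinh), t_avg, the curve
    slope at t_avg and the VoI; sorted by VoI descending.  Taxon sets must
    match exactly.
    """
    voi_by_taxon = {v.taxon: v for v in vois}
    bias_by_taxon = {b.taxon: b for b in bias}
    unmatched = set(voi_by_taxon) ^ set(bias_by_taxon)
    if unmatched:
        raise ValueError(
            f"unmatched taxa between VoI and bias tables: "
            f"{', '.join(sorted(unmatched))}")
    rows = []
    for taxon in sorted(voi_by_taxon):
        v, b = voi_by_taxon[taxon], bias_by_taxon[taxon]
        rows.append((taxon, b.n_x, b.s_x, b.r_x, b.r_x_asinh,
                     v.t_avg, v.slope_at_t, v.voi))
    df = pd.DataFrame(rows, columns=["taxon", "n_x", "s_x", "r_x",
                                     "r_x_asinh", "t_avg", "slope_at_t",
                                     "voi"])
    return df.sort_values("voi", ascending=False, ignore_index=True)


def fits_to_frame(fits: Sequence[CurveFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.taxon, f.params.l_inf, f.params.k, f.params.t0, f.params.b,
          f.n_points, f.rss, f.converged, f.message) for f in fits],
        columns=["taxon", "l_inf", "k", "t0", "b", "n_points", "rss",
                 "converged", "message"])


def fits_from_frame(df: pd.DataFrame) -> list[CurveFit]:
    return [CurveFit(taxon=str(r.taxon),
                     params=VBGFParams(float(r.l_inf), float(r.k),
                                       float(r.t0)),
                     n_points=int(r.n_points), rss=float(r.rss),
                     converged=bool(r.converged), message=str(r.message))
            for r in df.itertuples(index=False)]
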