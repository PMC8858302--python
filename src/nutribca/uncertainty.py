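"""Uncertainty analysis: correlated Monte Carlo PSA and one-way tornado.

Six inputs are varied, mirroring the sensitivity design of the evaluation:
stunting cases and deaths averted (bivariate normal, r = 0.55), the wage
premium, GNI-per-capita growth, the share of supplemental production sold,
and the intervention cost (independent uniforms). The VSL is held fixed at
the US-extrapolation value — the smallest of the four transfers, so varying
it could only inflate returns. Each draw re-prices all three benefit streams
at the base-case discount rate; the agriculture stream keeps its calibrated
annual base and re-evaluates the mixed-growth factor with the drawn growth
rate and sold share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discounting import growth_discount_sum
from .params import MonteCarloSpec, ParameterSet, paper_base_case
from .valuation import bca_summary, vsl_transfer

__all__ = [
    "PSAResult",
    "TornadoResult",
    "draw_correlated_pair",
    "evaluate_bcr",
    "run_psa",
    "one_way_tornado",
]


def draw_correlated_pair(
    mc: MonteCarloSpec, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw ``n`` correlated (stunting, deaths) pairs.

    Bivariate normal with marginals ``N(stunting_mean, stunting_sd^2)`` and
    ``N(deaths_mean, deaths_sd^2)`` and correlation ``rho``, built from two
    independent standard normals via the triangular (Cholesky) transform.
    """
    if not -1.0 < mc.rho < 1.0:
        raise ValueError(f"correlation must lie in (-1, 1), got {mc.rho}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    z = rng.standard_normal((2, n))
    stunting = mc.stunting_mean + mc.stunting_sd * z[0]
    deaths = mc.deaths_mean + mc.deaths_sd * (mc.rho * z[0] + np.sqrt(1.0 - mc.rho**2) * z[1])
    return np.column_stack([stunting, deaths])


def evaluate_bcr(
    params: ParameterSet,
    d: float,
    stunting=None,
    deaths=None,
    wage_premium=None,
    gni_growth=None,
    share_sold=None,
    total_cost=None,
    return_components: bool = False,
):
    """BCR at discount rate ``d`` with selected inputs overridden.

    Overrides may be scalars or equal-length arrays (vectorized across
    Monte Carlo draws). Unset inputs take their base values from ``params``.
    This single kernel backs both the PSA and the tornado so the two
    analyses cannot drift apart.
    """
    S = np.asarray(params.stunting_cases_averted if stunting is None else stunting, float)
    D = np.asarray(params.deaths_averted_unrounded if deaths is None else deaths, float)
    wp = np.asarray(params.wage_premium if wage_premium is None else wage_premium, float)
    g = np.asarray(params.gni_growth if gni_growth is None else gni_growth, float)
    s = np.asarray(params.share_sold if share_sold is None else share_sold, float)
    C = np.asarray(params.total_cost if total_cost is None else total_cost, float)

    vsl_usd = vsl_transfer("us_extrapolation", params).value_usd
    mortality = D * vsl_usd

    w_stunted = params.avg_wage / (1.0 + wp * (1.0 - params.stunting_prevalence))
    t0 = params.work_start_age - params.child_age_2016
    t1 = params.work_end_age - params.child_age_2016
    productivity = (S - D) * wp * w_stunted * growth_discount_sum(g, d, t0, t1, 1.0)

    agriculture = params.ag_base_annual_value * growth_discount_sum(g, d, 1, params.ag_years, s)

    total = mortality + productivity + agriculture
    bcr = total / C
    if return_components:
        return {
            "mortality": mortality,
            "productivity": productivity,
            "agriculture": agriculture,
            "total_benefit": total,
            "net_benefit": total - C,
            "bcr": bcr,
        }
    return bcr


@dataclass
class PSAResult:
    """Draw matrix and summary statistics of the probabilistic sensitivity analysis."""

    draws: pd.DataFrame
    discount_rate: float
    base_bcr: float
    seed: int
    n_draws: int
    mean_bcr: float
    median_bcr: float
    min_bcr: float
    max_bcr: float
    frac_bcr_gt_1: float
    frac_positive_net: float
    frac_bcr_gt_base: float

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "n_draws": self.n_draws,
                "seed": self.seed,
                "discount_rate": self.discount_rate,
                "base_bcr": self.base_bcr,
                "mean_bcr": self.mean_bcr,
                "median_bcr": self.median_bcr,
                "min_bcr": self.min_bcr,
                "max_bcr": self.max_bcr,
                "frac_bcr_gt_1": self.frac_bcr_gt_1,
                "frac_positive_net": self.frac_positive_net,
                "frac_bcr_gt_base": self.frac_bcr_gt_base,
            }
        )

    def bcr_histogram(self, width: float = 1.0) -> pd.DataFrame:
        """BCR histogram with fixed-width bins starting at 0."""
        bcr = self.draws["bcr"].to_numpy()
        edges = np.arange(0.0, np.ceil(bcr.max() / width) * width + width, width)
        counts, _ = np.histogram(bcr, bins=edges)
        return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})

    def to_dict(self, include_draws: bool = False) -> dict:
        d = {k: v for k, v in self.summary().items()}
        if include_draws:
            d["draws"] = self.draws.to_dict("list")
        return d


def run_psa(
    params: ParameterSet | None = None,
    n_draws: int | None = None,
    seed: int | None = None,
    d: float | None = None,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Defaults come from ``params.mc`` (1,000 draws) and the base-case
    discount rate. Identical seed and spec give bit-identical results.
    """
    if params is None:
        params = paper_base_case()
    mc = params.mc
    if n_draws is None:
        n_draws = mc.n_draws
    if seed is None:
        seed = mc.seed
    if d is None:
        d = params.base_case_rate
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")

    rng = np.random.default_rng(seed)
    pairs = draw_correlated_pair(mc, n_draws, rng)
    wp = rng.uniform(*mc.wage_premium_range, n_draws)
    g = rng.uniform(*mc.growth_range, n_draws)
    s = rng.uniform(*mc.share_sold_range, n_draws)
    cost = rng.uniform(*mc.cost_range, n_draws)

    comp = evaluate_bcr(
        params, d,
        stunting=pairs[:, 0], deaths=pairs[:, 1],
        wage_premium=wp, gni_growth=g, share_sold=s, total_cost=cost,
        return_components=True,
    )
    draws = pd.DataFrame(
        {
            "stunting": pairs[:, 0],
            "deaths": pairs[:, 1],
            "wage_premium": wp,
            "gni_growth": g,
            "share_sold": s,
            "total_cost": cost,
            **comp,
        }
    )
    bcr = draws["bcr"].to_numpy()
    base_bcr = bca_summary(params, d).bcr
    return PSAResult(
        draws=draws,
        discount_rate=d,
        base_bcr=base_bcr,
        seed=seed,
        n_draws=n_draws,
        mean_bcr=float(bcr.mean()),
        median_bcr=float(np.median(bcr)),
        min_bcr=float(bcr.min()),
        max_bcr=float(bcr.max()),
        frac_bcr_gt_1=float((bcr > 1.0).mean()),
        frac_positive_net=float((draws["net_benefit"].to_numpy() > 0.0).mean()),
        frac_bcr_gt_base=float((bcr > base_bcr).mean()),
    )


@dataclass
class TornadoResult:
    """One-way sensitivity table ordered by BCR swing (largest first)."""

    table: pd.DataFrame
    base_bcr: float
    discount_rate: float


def one_way_tornado(params: ParameterSet | None = None, d: float | None = None) -> TornadoResult:
    """Deterministic one-way sensitivity analysis of the BCR.

    Each varied input moves to its low/high bound while everything else
    stays at base. Uniform inputs use their distribution ranges; the two
    normal inputs use mean +/- one standard deviation.
    """
    if params is None:
        params = paper_base_case()
    if d is None:
        d = params.base_case_rate
    mc = params.mc
    bounds = {
        "stunting_cases_averted": (mc.stunting_mean - mc.stunting_sd, mc.stunting_mean + mc.stunting_sd),
        "deaths_averted": (mc.deaths_mean - mc.deaths_sd, mc.deaths_mean + mc.deaths_sd),
        "wage_premium": mc.wage_premium_range,
        "gni_growth": mc.growth_range,
        "share_sold": mc.share_sold_range,
        "total_cost": mc.cost_range,
    }
    override_key = {
        "stunting_cases_averted": "stunting",
        "deaths_averted": "deaths",
        "wage_premium": "wage_premium",
        "gni_growth": "gni_growth",
        "share_sold": "share_sold",
        "total_cost": "total_cost",
    }
    base_bcr = bca_summary(params, d).bcr
    rows = []
    for name, (lo, hi) in bounds.items():
        key = override_key[name]
        bcr_lo = float(evaluate_bcr(params, d, **{key: lo}))
        bcr_hi = float(evaluate_bcr(params, d, **{key: hi}))
        rows.append(
            {
                "parameter": name,
                "low": lo,
                "high": hi,
                "bcr_low": bcr_lo,
                "bcr_high": bcr_hi,
                "swing": abs(bcr_hi - bcr_lo),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("swing", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return TornadoResult(table=table, base_bcr=base_bcr, discount_rate=d)
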