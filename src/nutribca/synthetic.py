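"""Synthetic inputs with the statistical structure the analysis assumes.

No microdata are distributed with the evaluation, so this module generates
stand-ins for the two upstream datasets: a two-arm cluster-randomized trial
with binary stunting outcomes at baseline and endline (60 childcare-center
clusters, configurable difference-in-differences effect), and an itemized
program/community cost ledger whose valued aggregate hits configurable
totals. Both are seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .costing import CostItem, valued_amount
from .discounting import annuity_factor
from .params import ParameterSet, paper_base_case

__all__ = ["SyntheticTrial", "SyntheticLedger", "simulate_trial", "simulate_cost_ledger"]

_PROB_CLIP = (0.01, 0.99)


@dataclass
class SyntheticTrial:
    """Child-level records plus the generating parameters."""

    data: pd.DataFrame  # columns: cluster, arm, period, child, stunted
    p0: float
    effect_pp: float
    cluster_sd: float
    seed: int | None


def simulate_trial(
    n_clusters: int = 60,
    n_per_cluster: int = 5,
    p0: float = 0.37,
    effect_pp: float = -17.0,
    cluster_sd: float = 0.3,
    seed: int | None = None,
) -> SyntheticTrial:
    """Simulate a two-arm, two-period cluster trial with binary stunting.

    Both arms start at baseline prevalence ``p0``; at endline the control
    arm stays at ``p0`` while the treatment arm moves to
    ``p0 + effect_pp/100``. Each cluster carries a normal random effect on
    the logit scale (sd ``cluster_sd``) shared across periods, so the DID
    estimator removes it in expectation; cell probabilities are clipped to
    [0.01, 0.99]. Clusters split evenly between arms.
    """
    p1 = p0 + effect_pp / 100.0
    if not (0.0 < p0 < 1.0) or not (0.0 < p1 < 1.0):
        raise ValueError(f"prevalences must lie in (0,1): baseline {p0}, treated endline {p1}")
    if n_clusters < 2 or n_per_cluster < 1:
        raise ValueError("need at least 2 clusters and 1 child per cluster")
    if cluster_sd < 0:
        raise ValueError("cluster_sd must be >= 0")
    rng = np.random.default_rng(seed)
    arms = np.array(["treatment", "control"])[np.arange(n_clusters) % 2]
    u = rng.normal(0.0, cluster_sd, n_clusters)

    frames = []
    for period in ("baseline", "endline"):
        target = np.where((arms == "treatment") & (period == "endline"), p1, p0)
        p_cluster = np.clip(expit(logit(target) + u), *_PROB_CLIP)
        stunted = rng.random((n_clusters, n_per_cluster)) < p_cluster[:, None]
        frames.append(
            pd.DataFrame(
                {
                    "cluster": np.repeat(np.arange(n_clusters), n_per_cluster),
                    "arm": np.repeat(arms, n_per_cluster),
                    "period": period,
                    "child": np.tile(np.arange(n_per_cluster), n_clusters),
                    "stunted": stunted.ravel().astype(int),
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    return SyntheticTrial(data=data, p0=p0, effect_pp=effect_pp, cluster_sd=cluster_sd, seed=seed)


@dataclass
class SyntheticLedger:
    """Generated cost items plus the totals they were drawn to match."""

    items: list[CostItem]
    program_target: float
    community_target: float
    seed: int | None


_INPUT_POOL = ["personnel", "agricultural inputs", "food", "consumables", "training", "transport", "other"]


def simulate_cost_ledger(
    program_target: float = 147_916.0,
    community_target: float = 49_461.0,
    n_items: int = 12,
    seed: int | None = None,
    params: ParameterSet | None = None,
) -> SyntheticLedger:
    """Simulate an itemized ledger whose valued aggregate hits the targets.

    Items are spread over random activity/input categories and always
    include one capital item (10-year life, entered at its annuitized
    value) and one community volunteer-time item (entered at the shadow
    wage). Valued contributions per payer are drawn from a Dirichlet split
    of the target, then monetary amounts (or hours / purchase prices) are
    backed out so aggregation reproduces the targets to rounding error.
    """
    if program_target < 0 or community_target < 0:
        raise ValueError("targets must be >= 0")
    if n_items < 2:
        raise ValueError("need n_items >= 2 (one per payer)")
    if params is None:
        params = paper_base_case()
    rng = np.random.default_rng(seed)

    n_program = max(1, round(n_items * program_target / max(program_target + community_target, 1.0)))
    n_program = min(n_program, n_items - 1)
    n_community = n_items - n_program

    def split(total: float, k: int) -> np.ndarray:
        if total == 0:
            return np.zeros(k)
        return rng.dirichlet(np.ones(k) * 2.0) * total

    items: list[CostItem] = []
    # program items: first one is capital, rest plain amounts
    values = split(program_target, n_program)
    for i, v in enumerate(values):
        if i == 0:
            life = 10.0
            purchase = v * annuity_factor(params.capital_discount_rate, life)
            items.append(
                CostItem(
                    label="capital equipment",
                    activity="start-up",
                    input_category="capital",
                    payer="program",
                    amount=purchase,
                    useful_life_y=life,
                )
            )
        else:
            items.append(
                CostItem(
                    label=f"program item {i}",
                    activity=str(rng.choice(["start-up", "recurrent"])),
                    input_category=str(rng.choice(_INPUT_POOL)),
                    payer="program",
                    amount=float(v),
                )
            )
    # community items: first one is volunteer time, rest in-kind amounts
    values = split(community_target, n_community)
    hourly = params.shadow_wage_share * params.monthly_min_wage / params.hours_per_month
    for i, v in enumerate(values):
        if i == 0:
            items.append(
                CostItem(
                    label="volunteer meal preparation time",
                    activity="recurrent",
                    input_category="beneficiary time",
                    payer="community",
                    hours=float(v / hourly) if hourly > 0 else 0.0,
                )
            )
        else:
            items.append(
                CostItem(
                    label=f"community item {i}",
                    activity="recurrent",
                    input_category=str(rng.choice(["food", "consumables", "other"])),
                    payer="community",
                    amount=float(v),
                )
            )

    # final adjustment: absorb float error into the last plain-amount item per payer
    for payer, target in (("program", program_target), ("community", community_target)):
        idx = [i for i, it in enumerate(items) if it.payer == payer and it.hours is None and it.input_category != "capital"]
        if idx:
            current = sum(valued_amount(it, params) for it in items if it.payer == payer)
            adj = target - current
            last = items[idx[-1]]
            if last.amount + adj < 0:
                raise ValueError(f"infeasible {payer} target {target}")
            items[idx[-1]] = last.model_copy(update={"amount": last.amount + adj})

    return SyntheticLedger(
        items=items, program_target=program_target, community_target=community_target, seed=seed
    )
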