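"""Present-value kernels shared by the costing and valuation layers.

Two primitives cover every discounted sum in the model: a plain annuity
factor (used to annuitize capital and to discount years of life lost) and a
growth-discount sum in which a configurable share of each year's payment
appreciates at a growth rate while the remainder stays at constant prices.
"""

from __future__ import annotations

import numpy as np

__all__ = ["annuity_factor", "growth_discount_sum"]


def annuity_factor(rate: float, n_years: float) -> float:
    """Present value of a 1-unit payment at the end of each of ``n_years`` years.

    Equals ``(1 - (1 + r)**-T) / r`` and continuously extends to ``T`` at
    ``r = 0``. ``n_years`` may be fractional (used for remaining life
    expectancies such as 79.05 years).

    Parameters
    ----------
    rate : float
        Annual discount rate, >= 0.
    n_years : float
        Number of annual payments, >= 0.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if n_years < 0:
        raise ValueError(f"n_years must be >= 0, got {n_years}")
    if rate == 0:
        return float(n_years)
    return (1.0 - (1.0 + rate) ** -n_years) / rate


def growth_discount_sum(growth, discount, t_start: int, t_end: int, grow_share=1.0):
    """Discounted sum of a partially growing payment stream.

    Computes ``sum_{t=t_start..t_end} [s (1+g)^t + (1-s)] / (1+d)^t`` where
    ``s`` is the share of each year's unit payment that appreciates at rate
    ``g``; the remaining ``1-s`` is held at constant (year-0) prices. With
    ``s=1, g=0`` this reduces to the ordinary annuity factor over the window.

    ``growth``, ``discount`` and ``grow_share`` broadcast as numpy arrays,
    which lets the Monte Carlo layer evaluate thousands of draws in one call.
    Returns a float for scalar inputs, an ndarray otherwise.
    """
    if t_start > t_end:
        raise ValueError(f"t_start ({t_start}) must be <= t_end ({t_end})")
    g = np.asarray(growth, dtype=float)
    d = np.asarray(discount, dtype=float)
    s = np.asarray(grow_share, dtype=float)
    if np.any(g <= -1) or np.any(d <= -1):
        raise ValueError("growth and discount rates must be > -1")
    t = np.arange(t_start, t_end + 1)
    grown = (1.0 + g)[..., np.newaxis] ** t
    disc = (1.0 + d)[..., np.newaxis] ** t
    terms = (s[..., np.newaxis] * grown + (1.0 - s)[..., np.newaxis]) / disc
    out = terms.sum(axis=-1)
    if out.ndim == 0:
        return float(out)
    return out
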