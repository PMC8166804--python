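"""Discrete annual annuity discounting used across the model.

Streams that run for ``years`` at one unit per year are valued with the
standard annuity factor ``(1 - (1 + r)^-years) / r``; the r -> 0 limit is
``years``.  The same convention prices forgone income, years of life
lost, and the funeral bring-forward differential, keeping the three
consistent with each other.
"""

from __future__ import annotations

import numpy as np


def annuity_factor(rate: float, years) -> np.ndarray | float:
    """Present value of 1/year for ``years`` years at discount ``rate``.

    Accepts scalar or array ``years`` (may be fractional); negative years
    are treated as zero.
    """
    y = np.maximum(np.asarray(years, dtype=float), 0.0)
    if rate == 0.0:
        out = y
    else:
        out = (1.0 - (1.0 + rate) ** (-y)) / rate
    if np.ndim(years) == 0:
        return float(out)
    return out


def bring_forward_factor(rate: float, years) -> np.ndarray | float:
    """Cost share of bringing a one-off payment forward by ``years`` years.

    ``1 - (1 + r)^-years``: the difference between paying now and paying
    ``years`` years later, per unit of payment.  Zero at r = 0 or years = 0.
    """
    y = np.maximum(np.asarray(years, dtype=float), 0.0)
    out = 1.0 - (1.0 + rate) ** (-y)
    if np.ndim(years) == 0:
        return float(out)
    return out
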