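"""The double-logistic seasonal curve family.

The seasonal greenness/productivity model used throughout the package is

    y(t) = b + a * [ expit(k (t - m)) - expit(r (t - n)) ]

where ``expit(x) = 1 / (1 + exp(-x))``: a rising logistic with inflection at
``m`` (spring, rate ``k``) minus a second rising logistic with inflection at
``n`` (autumn, rate ``r``), so the curve climbs from the winter background
``b`` to a summer plateau of about ``a + b`` and returns to ``b``.  ``a`` is
the seasonal amplitude, ``b`` the background value.

The second derivative of the spring limb alone has its (first) local maximum
at ``t = m - ln(2 + sqrt(3)) / k``; the autumn limb contributes a second
local maximum at ``t = n + ln(2 + sqrt(3)) / r``.  These closed forms anchor
the curvature-based season-start/-end extractor.
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit

#: offset (in units of 1/rate) between a logistic inflection and the
#: adjacent local maximum of its second derivative: ln(2 + sqrt(3))
INFLECTION_OFFSET = float(np.log(2.0 + np.sqrt(3.0)))


def double_logistic(t, a, b, k, m, r, n):
    """Evaluate the double-logistic seasonal curve at times ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    return b + a * (expit(k * (t - m)) - expit(r * (t - n)))


def double_logistic_d2(t, a, b, k, m, r, n):
    """Exact second time-derivative of :func:`double_logistic`."""
    t = np.asarray(t, dtype=float)
    s1 = expit(k * (t - m))
    s2 = expit(r * (t - n))
    d2_rise = k ** 2 * s1 * (1.0 - s1) * (1.0 - 2.0 * s1)
    d2_fall = r ** 2 * s2 * (1.0 - s2) * (1.0 - 2.0 * s2)
    return a * (d2_rise - d2_fall)


def plateau_value(a, b, k, m, r, n):
    """Curve value at the plateau midpoint (m + n) / 2."""
    return float(double_logistic(0.5 * (m + n), a, b, k, m, r, n))
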