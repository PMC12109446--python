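"""Single- vs dual-task comparison statistics and Bland–Altman agreement.

Paired two-sided t tests compare per-subject parameter means between
walking conditions (STW vs VFT/PTW); no multiple-testing correction is
applied by default, mirroring the conventional per-parameter presentation,
with Holm correction available as an option.  Bland–Altman summaries use
the signed convention (model detection − reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats


@dataclass
class PairedComparison:
    parameter: str
    task_a: str
    task_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def paired_ttest(
    values_a: np.ndarray,
    values_b: np.ndarray,
    parameter: str = "",
    task_a: str = "a",
    task_b: str = "b",
) -> PairedComparison:
    """Two-sided paired t test on per-subject condition means.

    Degenerate cases are resolved by convention: identical vectors give
    t = 0, p = 1; a nonzero constant difference (zero variance) gives
    p = 0 with a signed infinite t.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be equal-length and 1-D")
    if len(a) < 2:
        raise ValueError("need n >= 2 pairs")
    diff = a - b
    if np.all(diff == diff[0]):
        if diff[0] == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(diff[0]) * np.inf), 0.0
    else:
        t, p = spstats.ttest_rel(a, b)
    return PairedComparison(
        parameter=parameter,
        task_a=task_a,
        task_b=task_b,
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
        t_statistic=float(t),
        p_value=float(p),
        n=len(a),
    )


def compare_conditions(
    params_a: list[dict],
    params_b: list[dict],
    task_a: str = "STW",
    task_b: str = "VFT",
    holm: bool = False,
) -> list[PairedComparison]:
    """Paired comparisons for every shared gait parameter.

    ``params_a[i]`` and ``params_b[i]`` are the same subject's per-trial
    parameter dicts under the two conditions.
    """
    if len(params_a) != len(params_b):
        raise ValueError("condition lists must pair subjects one-to-one")
    names = [k for k in params_a[0] if k in params_b[0]]
    results = [
        paired_ttest(
            np.asarray([d[name] for d in params_a]),
            np.asarray([d[name] for d in params_b]),
            parameter=name,
            task_a=task_a,
            task_b=task_b,
        )
        for name in names
    ]
    if holm:
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        adjusted, running = {}, 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * results[idx].p_value)
            adjusted[idx] = min(1.0, running)
        for idx, r in enumerate(results):
            r.p_value = adjusted[idx]
    return results


@dataclass
class BlandAltman:
    """Bias and ±1.96 SD limits of agreement of signed differences."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int
    group: str = "pooled"


def bland_altman(
    detected: np.ndarray, reference: np.ndarray, group: str = "pooled"
) -> BlandAltman:
    """Agreement summary for matched detected/reference event times.

    Differences are detected − reference; limits of agreement are
    bias ± 1.96·SD (sample SD, ddof=1; 0 for n constant differences).
    """
    d = np.asarray(detected, dtype=float)
    r = np.asarray(reference, dtype=float)
    if d.shape != r.shape or d.ndim != 1:
        raise ValueError("detected and reference must be equal-length 1-D arrays")
    if len(d) < 2:
        raise ValueError("need >= 2 matched pairs")
    diff = d - r
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=len(diff),
        group=group,
    )
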