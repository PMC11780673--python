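"""Consensus verdicts, confusion tables, and diagnostic metrics with Wilson CIs.

The reference standard is the majority opinion (mode) of a human panel;
the test under evaluation is the mode of repeated model runs. Verdicts
are ternary: ``True``, ``False``, or ``None`` (an explicit NA/abstain).
Sensitivity, specificity, PPV and NPV are binomial proportions and carry
Wilson score intervals; F1 and balanced accuracy are derived from them
and are reported without intervals. Cross-sign summaries are median and
IQR over the per-sign values.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

Verdict = bool | None

COUNT_METRICS = ("sensitivity", "specificity", "ppv", "npv")
DERIVED_METRICS = ("f1", "balanced_accuracy")
Z95 = 1.959963984540054

__all__ = [
    "ConfusionTable",
    "MetricEstimate",
    "PanelSummary",
    "mode_verdict",
    "confusion",
    "wilson_ci",
    "performance_metrics",
    "summarize_across_signs",
]


def mode_verdict(verdicts: Sequence[Verdict]) -> Verdict:
    """Majority verdict of a panel; ties and all-NA panels yield NA.

    NA entries are removed first; a strict majority of the remainder is
    required. An exact true/false tie is itself an undefined consensus
    (NA) — such questions are later excluded from confusion tables
    rather than broken arbitrarily.
    """
    if len(verdicts) == 0:
        raise ValueError("empty verdict list")
    counts = Counter(v for v in verdicts if v is not None)
    if not counts:
        return None
    n_true, n_false = counts.get(True, 0), counts.get(False, 0)
    if n_true == n_false:
        return None
    return n_true > n_false


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts plus the number of questions excluded for NA consensus."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    excluded: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.excluded

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.excluded + other.excluded,
        )


def confusion(
    reference: Mapping[Hashable, Verdict],
    test: Mapping[Hashable, Verdict],
) -> ConfusionTable:
    """Tabulate test consensus against reference consensus on aligned questions.

    Questions where either consensus is NA are counted as ``excluded``.
    The two mappings must cover exactly the same keys.
    """
    missing = set(reference) ^ set(test)
    if missing:
        raise KeyError(f"question keys not shared by both sides: {sorted(missing)[:10]}")
    tp = fp = tn = fn = excluded = 0
    for key, ref in reference.items():
        tst = test[key]
        if ref is None or tst is None:
            excluded += 1
        elif ref and tst:
            tp += 1
        elif ref and not tst:
            fn += 1
        elif tst:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn, excluded=excluded)


def wilson_ci(k: int, n: int, z: float = Z95) -> tuple[float, float] | None:
    """Wilson score interval for a binomial proportion k/n.

    Returns ``None`` when n == 0 (undefined metric marker, not an
    exception). Bounds are clipped to [0, 1]; at k == 0 and k == n the
    closed boundary is exact.
    """
    if n == 0:
        return None
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2.0 * n)) / denom
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    # the closed boundary is exact at p in {0, 1}; avoid round-off there
    low = 0.0 if k == 0 else max(0.0, center - half)
    high = 1.0 if k == n else min(1.0, center + half)
    return (low, high)


@dataclass(frozen=True)
class MetricEstimate:
    """A metric value with its counts and, for count-based metrics, a Wilson CI."""

    name: str
    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    k: int | None = None
    n: int | None = None
    z: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


def _proportion(name: str, k: int, n: int, z: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(name, None, k=k, n=n, z=z)
    ci = wilson_ci(k, n, z)
    assert ci is not None
    return MetricEstimate(name, k / n, ci_low=ci[0], ci_high=ci[1], k=k, n=n, z=z)


def performance_metrics(ct: ConfusionTable, z: float = Z95) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity, PPV, NPV (each with Wilson CI), F1 and balanced accuracy.

    F1 is the harmonic mean of sensitivity and PPV; balanced accuracy is
    the arithmetic mean of sensitivity and specificity. A zero
    denominator yields an undefined marker that propagates into the
    derived metrics.
    """
    se = _proportion("sensitivity", ct.tp, ct.tp + ct.fn, z)
    sp = _proportion("specificity", ct.tn, ct.tn + ct.fp, z)
    ppv = _proportion("ppv", ct.tp, ct.tp + ct.fp, z)
    npv = _proportion("npv", ct.tn, ct.tn + ct.fn, z)

    if se.defined and ppv.defined and (se.value + ppv.value) > 0:
        f1 = MetricEstimate("f1", 2.0 * se.value * ppv.value / (se.value + ppv.value))
    else:
        f1 = MetricEstimate("f1", None)
    if se.defined and sp.defined:
        ba = MetricEstimate("balanced_accuracy", (se.value + sp.value) / 2.0)
    else:
        ba = MetricEstimate("balanced_accuracy", None)
    return {m.name: m for m in (se, sp, ppv, npv, f1, ba)}


@dataclass(frozen=True)
class PanelSummary:
    """Median and IQR of one metric across signs, with undefined-value count."""

    metric: str
    median: float | None
    q1: float | None
    q3: float | None
    n_defined: int
    n_undefined: int


def summarize_across_signs(
    per_sign: Mapping[str, Mapping[str, MetricEstimate]],
    metrics: Iterable[str] = COUNT_METRICS + DERIVED_METRICS,
) -> dict[str, PanelSummary]:
    """Median and IQR of each metric over signs, omitting undefined values.

    Quartiles use linear interpolation between order statistics (the
    default convention of most statistical environments); pass the
    per-sign metric dict produced by :func:`performance_metrics`.
    """
    out: dict[str, PanelSummary] = {}
    for metric in metrics:
        values = [
            per_sign[sign][metric].value
            for sign in per_sign
            if metric in per_sign[sign] and per_sign[sign][metric].defined
        ]
        n_undef = len(per_sign) - len(values)
        if not values:
            out[metric] = PanelSummary(metric, None, None, None, 0, n_undef)
            continue
        q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
        out[metric] = PanelSummary(metric, float(med), float(q1), float(q3), len(values), n_undef)
    return out
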