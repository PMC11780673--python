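"""Reproducibility statistics: pairwise Cohen's kappa and McNemar's test.

Cohen's kappa measures chance-corrected agreement between two verdict
vectors and is averaged over all unique respondent pairs (human pairs,
or pairs of repeated model runs at one temperature). McNemar's test
compares two paired classifiers through their discordant counts, with
the continuity correction clamped at zero so that equal discordant
counts give chi-square exactly 0 rather than a positive artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import pandas as pd
from scipy.stats import chi2

from .metrics import Verdict

__all__ = ["KappaResult", "McNemarResult", "cohens_kappa", "pairwise_mean_kappa", "mcnemar"]


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_o: float
    p_e: float
    n_pairs: int
    n_dropped: int


@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    chi2: float
    p_value: float
    df: int = 1


def _drop_na(v1: Sequence[Verdict], v2: Sequence[Verdict]) -> tuple[list[bool], list[bool], int]:
    if len(v1) != len(v2):
        raise ValueError(f"verdict vectors differ in length: {len(v1)} vs {len(v2)}")
    a, b, dropped = [], [], 0
    for x, y in zip(v1, v2):
        if x is None or y is None:
            dropped += 1
        else:
            a.append(x)
            b.append(y)
    return a, b, dropped


def cohens_kappa(v1: Sequence[Verdict], v2: Sequence[Verdict]) -> KappaResult | None:
    """Cohen's kappa between two aligned verdict vectors.

    Pairs with NA on either side are dropped (and counted). Observed
    agreement p_o is the fraction of identical verdicts; chance
    agreement p_e comes from each vector's own true/false marginals.
    Returns ``None`` when no usable pairs remain. Perfect agreement with
    degenerate marginals (p_e == 1) is reported as kappa = 1.
    """
    a, b, dropped = _drop_na(v1, v2)
    n = len(a)
    if n == 0:
        return None
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p1, p2 = sum(a) / n, sum(b) / n
    p_e = p1 * p2 + (1.0 - p1) * (1.0 - p2)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=kappa, p_o=p_o, p_e=p_e, n_pairs=n, n_dropped=dropped)


def pairwise_mean_kappa(
    panel: Mapping[str, Mapping[Hashable, Verdict]],
) -> tuple[pd.DataFrame, float | None]:
    """Kappa for every unique respondent pair, plus the arithmetic mean.

    ``panel`` maps respondent id -> {question key -> verdict}. All
    respondents must cover the same question keys. Pairs with zero
    usable questions are excluded from the mean and flagged with a NaN
    kappa in the table. Returns (per-pair table, mean over defined pairs).
    """
    if len(panel) < 2:
        raise ValueError("need at least two respondents")
    ids = list(panel)
    keys = sorted(panel[ids[0]], key=repr)
    for rid in ids[1:]:
        if set(panel[rid]) != set(keys):
            raise KeyError(f"respondent {rid!r} covers different question keys")
    rows = []
    for r1, r2 in combinations(ids, 2):
        res = cohens_kappa([panel[r1][k] for k in keys], [panel[r2][k] for k in keys])
        rows.append(
            {
                "respondent_1": r1,
                "respondent_2": r2,
                "kappa": res.kappa if res else float("nan"),
                "p_o": res.p_o if res else float("nan"),
                "p_e": res.p_e if res else float("nan"),
                "n_pairs": res.n_pairs if res else 0,
                "n_dropped": res.n_dropped if res else len(keys),
            }
        )
    table = pd.DataFrame(rows)
    defined = table["kappa"].dropna()
    mean = float(defined.mean()) if len(defined) else None
    return table, mean


def mcnemar(v1: Sequence[Verdict], v2: Sequence[Verdict]) -> McNemarResult:
    """McNemar's chi-square test with continuity correction, 1 df.

    b counts questions where the first classifier says true and the
    second false; c the converse. chi2 = max(|b-c| - 1, 0)^2 / (b + c);
    when b + c = 0 the statistic is 0 and p = 1 by convention. NA pairs
    are dropped.
    """
    a, b_, _ = _drop_na(v1, v2)
    b = sum(x and not y for x, y in zip(a, b_))
    c = sum(y and not x for x, y in zip(a, b_))
    if b + c == 0:
        return McNemarResult(b=b, c=c, chi2=0.0, p_value=1.0)
    stat = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    return McNemarResult(b=b, c=c, chi2=stat, p_value=float(chi2.sf(stat, df=1)))
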