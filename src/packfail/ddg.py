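"""ΔΔG benchmark statistics: Kd→ΔG conversion, classification, McNemar's test,
and SKEMPI-style record downsampling.

Binding free energies follow ΔG = R·T·ln(Kd) with R = 1.987×10⁻³
kcal/(mol·K); mutational effects are ΔΔG = ΔG_mut − ΔG_wt. Mutations are
classified as stabilizing (ΔΔG < −1 kcal/mol), destabilizing (ΔΔG > +1), or
neutral (the closed interval [−1, 1]). Paired classifier accuracies are
compared with McNemar's test on the discordant cells of a 2×2 contingency
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GAS_CONSTANT_KCAL",
    "CLASS_BOUNDARY",
    "ClassificationResult",
    "kd_to_dg",
    "dg_to_kd",
    "classify_ddg",
    "classification_result",
    "mcnemar",
    "skempi_downsample",
    "MUTATION_CATEGORIES",
]

GAS_CONSTANT_KCAL = 1.987e-3  # kcal / (mol K)
CLASS_BOUNDARY = 1.0          # kcal/mol
EXACT_MCNEMAR_MAX = 25        # switch to chi-square above this many discordant pairs

MUTATION_CATEGORIES = (
    "polar->polar",
    "polar->nonpolar",
    "nonpolar->polar",
    "nonpolar->nonpolar",
)


def kd_to_dg(kd: float | np.ndarray, temperature: float | np.ndarray) -> float | np.ndarray:
    """ΔG (kcal/mol) from a dissociation constant (molar) at temperature T (K)."""
    kd = np.asarray(kd, dtype=float)
    T = np.asarray(temperature, dtype=float)
    if np.any(kd <= 0) or np.any(T <= 0):
        raise ValueError("Kd and temperature must be positive")
    out = GAS_CONSTANT_KCAL * T * np.log(kd)
    return float(out) if out.ndim == 0 else out


def dg_to_kd(dg: float | np.ndarray, temperature: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`kd_to_dg`."""
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    out = np.exp(np.asarray(dg, dtype=float) / (GAS_CONSTANT_KCAL * T))
    return float(out) if out.ndim == 0 else out


def classify_ddg(ddg: float, boundary: float = CLASS_BOUNDARY) -> str:
    """Three-class label for a mutational ΔΔG (kcal/mol).

    The neutral interval is closed: exactly ±boundary is neutral.
    """
    if not math.isfinite(ddg):
        raise ValueError("ΔΔG must be finite")
    if ddg < -boundary:
        return "stabilizing"
    if ddg > boundary:
        return "destabilizing"
    return "neutral"


@dataclass
class ClassificationResult:
    """Per-mutation classes for two predictors against the truth."""

    true_class: list[str]
    pred_a: list[str]
    pred_b: list[str]

    @property
    def n(self) -> int:
        return len(self.true_class)

    def accuracy(self, which: str = "a") -> float:
        pred = self.pred_a if which == "a" else self.pred_b
        return sum(p == t for p, t in zip(pred, self.true_class)) / self.n

    def contingency(self) -> tuple[int, int, int, int]:
        """(both correct, only A correct, only B correct, both wrong)."""
        both = only_a = only_b = neither = 0
        for t, a, b in zip(self.true_class, self.pred_a, self.pred_b):
            ok_a, ok_b = a == t, b == t
            if ok_a and ok_b:
                both += 1
            elif ok_a:
                only_a += 1
            elif ok_b:
                only_b += 1
            else:
                neither += 1
        return both, only_a, only_b, neither


def classification_result(
    true_ddg: Sequence[float],
    pred_a: Sequence[float],
    pred_b: Sequence[float] | None = None,
    boundary: float = CLASS_BOUNDARY,
) -> ClassificationResult:
    """Classify measured and predicted ΔΔGs into the three categories."""
    t = [classify_ddg(x, boundary) for x in true_ddg]
    a = [classify_ddg(x, boundary) for x in pred_a]
    b = [classify_ddg(x, boundary) for x in (pred_b if pred_b is not None else pred_a)]
    return ClassificationResult(t, a, b)


def mcnemar(only_a: int, only_b: int) -> float:
    """Two-sided McNemar p-value from the discordant cell counts.

    Exact binomial test with p = ½ when only_a + only_b ≤ 25, otherwise the
    χ² approximation with continuity correction. Symmetric in its arguments;
    degenerate inputs (no discordant pairs) give p = 1.
    """
    if only_a < 0 or only_b < 0:
        raise ValueError("cell counts must be non-negative")
    n = only_a + only_b
    if n == 0:
        return 1.0
    if n <= EXACT_MCNEMAR_MAX:
        return float(stats.binomtest(only_a, n, 0.5).pvalue)
    chi2 = (abs(only_a - only_b) - 1) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))


def skempi_downsample(
    records: pd.DataFrame,
    target_n: int = 633,
    seed: int = 0,
    min_measurements_per_structure: int = 10,
) -> pd.DataFrame:
    """Filter and downsample binding records toward an even category split.

    Eligibility requires: the record's structure has at least
    ``min_measurements_per_structure`` measurements, the mutation was measured
    in a single-mutant context (``single_mutant``), and the assay temperature
    was known rather than assumed (``temperature_known``). Seeded uniform
    sampling then draws toward ``target_n / 4`` per mutational category;
    categories with fewer eligible records contribute everything they have and
    the shortfall is redistributed to the remaining categories.
    """
    eligible = records[
        records["single_mutant"].astype(bool)
        & records["temperature_known"].astype(bool)
    ]
    per_structure = eligible.groupby("complex_id")["complex_id"].transform("count")
    eligible = eligible[per_structure >= min_measurements_per_structure]
    if eligible.empty:
        raise ValueError("no eligible records after filtering")
    rng = np.random.default_rng(seed)
    cats = [c for c in MUTATION_CATEGORIES if (eligible["category"] == c).any()]
    base, extra = divmod(target_n, len(cats))
    quotas = {c: base + (1 if i < extra else 0) for i, c in enumerate(cats)}
    avail = {c: eligible[eligible["category"] == c] for c in cats}
    # hand shortfall from small categories to those with spare records
    while True:
        short = sum(max(0, quotas[c] - len(avail[c])) for c in cats)
        for c in cats:
            quotas[c] = min(quotas[c], len(avail[c]))
        if short == 0:
            break
        spare = {c: len(avail[c]) - quotas[c] for c in cats}
        room = [c for c in cats if spare[c] > 0]
        if not room:
            break
        for c in room:
            take = min(spare[c], short)
            quotas[c] += take
            short -= take
            if short == 0:
                break
    picks = []
    for c in cats:
        idx = avail[c].index.to_numpy()
        chosen = rng.choice(idx, size=quotas[c], replace=False)
        picks.append(records.loc[np.sort(chosen)])
    return pd.concat(picks).reset_index(drop=True)
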