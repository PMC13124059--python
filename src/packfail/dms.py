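"""Deep-mutational-scanning analysis: enrichment, EC50 inference, stability
scores, rescue calling, and biophysical mutation classification.

The experiment assayed here expresses a saturation-mutagenesis library of a
designed miniprotein on yeast, digests unstable variants with a protease at a
geometric series of concentrations, and deep-sequences the library before and
after each selection. A variant's EC50 — the protease concentration at which
half of it is degraded — is inferred from how its read counts deplete across
concentrations. Concentrations are indexed on the log scale of the dilution
series (index 0 = unselected), so EC50s and stability scores are expressed in
dilution-step units.

EC50 inference uses a Poisson count likelihood with a library-mean-survival
normalizer estimated self-consistently from all variants of a design; the
cell-sorting likelihood used by the original assay is intentionally not
reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EC50Estimate",
    "MutationClass",
    "NONPOLAR_AA",
    "SIDECHAIN_HEAVY_ATOMS",
    "DEFAULT_DILUTION_RATIO",
    "DEFAULT_HILL",
    "RESCUE_THRESHOLD",
    "enrichment",
    "fit_ec50",
    "fit_ec50_table",
    "stability_score",
    "aggregate_scores",
    "call_rescues",
    "classify_mutation",
    "dms_scores",
]

DEFAULT_DILUTION_RATIO = 3.0
DEFAULT_HILL = 2.0
DEFAULT_PSEUDOCOUNT = 0.5
RESCUE_THRESHOLD = 1.0

#: One-letter codes of residues with nonpolar sidechains.
NONPOLAR_AA = frozenset("AVLIMFWPGC")

#: Sidechain heavy-atom counts, the default size measure for mutations.
SIDECHAIN_HEAVY_ATOMS = {
    "A": 1, "R": 7, "N": 4, "D": 4, "C": 2, "Q": 5, "E": 5, "G": 0, "H": 6,
    "I": 4, "L": 4, "K": 5, "M": 4, "F": 7, "P": 3, "S": 2, "T": 3, "W": 10,
    "Y": 8, "V": 3,
}

_VARIANT_COLS = ["design_id", "site", "mutant_aa"]


class MissingVariantError(KeyError):
    """The requested variant is absent from the count table."""


class InsufficientDataError(ValueError):
    """Fewer than three usable concentration points for an EC50 fit."""


@dataclass(frozen=True)
class EC50Estimate:
    """EC50 in concentration-index units with a profile-likelihood 95% CI."""

    value: float
    ci95: tuple[float, float]
    censored: str | None = None  # 'low' | 'high' | None

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.value <= self.ci95[1]):
            raise ValueError("EC50 must lie inside its confidence interval")


@dataclass(frozen=True)
class MutationClass:
    polarity: str  # e.g. 'polar->nonpolar'
    size: str      # 'small->large' | 'large->small' | 'same'


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def enrichment(
    counts: pd.DataFrame,
    design_id: str,
    site: int,
    mutant_aa: str,
    protease: str,
    conc: int,
    replicate: int | str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Frequency after selection divided by frequency in the unselected library.

    Both frequencies are pseudocount-adjusted: (c + α) / T with column totals T.
    """
    sel = counts[
        (counts["protease"] == protease)
        & (counts["conc_index"] == conc)
        & (counts["replicate"] == replicate)
    ]
    unsel = counts[
        (counts["protease"] == protease)
        & (counts["conc_index"] == 0)
        & (counts["replicate"] == replicate)
    ]
    row_sel = sel[(sel["design_id"] == design_id) & (sel["site"] == site)
                  & (sel["mutant_aa"] == mutant_aa)]
    row_unsel = unsel[(unsel["design_id"] == design_id) & (unsel["site"] == site)
                      & (unsel["mutant_aa"] == mutant_aa)]
    if row_sel.empty or row_unsel.empty:
        raise MissingVariantError(f"{design_id}/{site}/{mutant_aa} not in table")
    f_sel = (row_sel["count"].iloc[0] + pseudocount) / (sel["count"].sum() + pseudocount)
    f_unsel = (row_unsel["count"].iloc[0] + pseudocount) / (unsel["count"].sum() + pseudocount)
    return float(f_sel / f_unsel)


# ---------------------------------------------------------------------------
# EC50 inference
# ---------------------------------------------------------------------------


def _survival(conc: np.ndarray, ec50: np.ndarray, hill: float, rho: float) -> np.ndarray:
    """Sigmoidal survival 1/(1 + (c/EC50)^h) on the log_ρ index scale."""
    expo = hill * (conc[None, :] - ec50[:, None]) * np.log(rho)
    expo = np.clip(expo, -500, 500)
    return 1.0 / (1.0 + np.exp(expo))


def fit_ec50_table(
    counts: pd.DataFrame,
    hill: float = DEFAULT_HILL,
    rho: float = DEFAULT_DILUTION_RATIO,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit EC50s for every variant × protease × replicate in a count table.

    The likelihood treats selected-column read counts as an absolute-abundance
    readout: the expected count of variant v at concentration index x is
    λ·f0_v·s_v(x), where λ is the unselected column total, f0_v the variant's
    unselected frequency, and s the sigmoidal survival curve. This requires
    sequencing depth to track the amount of surviving material across
    concentrations (which is what makes the absolute EC50 identifiable; a
    depth re-normalized to a fixed total would only identify EC50
    differences). Each variant's EC50 maximizes the Poisson log likelihood on
    a fixed grid; 95% CIs are profile-likelihood intervals from the same
    grid. EC50s outside the tested concentration range are clamped to the
    boundary and flagged censored.
    """
    if grid is None:
        grid = np.arange(-2.0, 10.0 + 1e-9, 0.04)
    out_rows = []
    for (design, protease, replicate), grp in counts.groupby(
        ["design_id", "protease", "replicate"], sort=False
    ):
        pivot = grp.pivot_table(
            index=["site", "mutant_aa"], columns="conc_index", values="count",
            aggfunc="sum", fill_value=0,
        )
        concs = np.array(sorted(c for c in pivot.columns if c != 0), dtype=float)
        if concs.size < 3:
            raise InsufficientDataError(
                f"{design}/{protease}/{replicate}: fewer than 3 concentrations"
            )
        c0 = pivot[0].to_numpy(dtype=float)
        lam = c0.sum()
        if lam <= 0:
            raise InsufficientDataError(
                f"{design}/{protease}/{replicate}: empty unselected column"
            )
        C = pivot[concs].to_numpy(dtype=float)
        f0 = (c0 + pseudocount) / (lam + pseudocount * len(c0))
        S = _survival(concs, grid, hill, rho)          # (G, X)
        # Poisson ll up to variant-constants: C·lnS − λ f0 Σ_x s
        ll = C @ np.log(S).T - np.outer(lam * f0, S.sum(axis=1))
        best = np.argmax(ll, axis=1)
        e_hat = grid[best]
        lo_conc, hi_conc = float(concs.min()), float(concs.max())
        llmax = ll[np.arange(ll.shape[0]), best]
        inside = ll >= (llmax[:, None] - 1.92)       # chi2_1 95% / 2
        for vi, (site, mut) in enumerate(pivot.index):
            sel = np.flatnonzero(inside[vi])
            ci = (float(grid[sel[0]]), float(grid[sel[-1]]))
            val = float(e_hat[vi])
            censored = None
            if val >= hi_conc:
                val, censored = hi_conc, "high"
            elif val <= lo_conc:
                val, censored = lo_conc, "low"
            ci = (min(ci[0], val), max(ci[1], val))
            out_rows.append(
                (design, site, mut, protease, replicate, val, ci[0], ci[1], censored)
            )
    return pd.DataFrame(
        out_rows,
        columns=_VARIANT_COLS + ["protease", "replicate", "ec50", "ci_lo", "ci_hi",
                                 "censored"],
    )


def fit_ec50(
    counts: pd.DataFrame,
    design_id: str,
    site: int,
    mutant_aa: str,
    protease: str,
    replicate: int | str,
    **kwargs,
) -> EC50Estimate:
    """EC50 for one variant; the joint per-design fit runs under the hood."""
    sub = counts[(counts["design_id"] == design_id)
                 & (counts["protease"] == protease)
                 & (counts["replicate"] == replicate)]
    if sub[(sub["site"] == site) & (sub["mutant_aa"] == mutant_aa)].empty:
        raise MissingVariantError(f"{design_id}/{site}/{mutant_aa} not in table")
    table = fit_ec50_table(sub, **kwargs)
    row = table[(table["site"] == site) & (table["mutant_aa"] == mutant_aa)].iloc[0]
    return EC50Estimate(
        float(row["ec50"]), (float(row["ci_lo"]), float(row["ci_hi"])),
        None if pd.isna(row["censored"]) else row["censored"],
    )


# ---------------------------------------------------------------------------
# Stability scores and aggregation
# ---------------------------------------------------------------------------


def stability_score(ec50_obs: EC50Estimate | float, ec50_unfolded: float) -> float:
    """Observed minus unfolded-state EC50 on the log-dilution index scale.

    Positive scores mean the variant withstands more protease than an
    unfolded chain of the same sequence would, i.e. it is folded.
    """
    obs = ec50_obs.value if isinstance(ec50_obs, EC50Estimate) else float(ec50_obs)
    return obs - float(ec50_unfolded)


def aggregate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-protease, per-replicate stability scores per variant.

    Within each replicate the score is the minimum across proteases (the
    harsher protease wins); replicate scores are then averaged. The output
    also carries replicate-averaged per-protease scores.
    """
    per_rep = (
        scores.groupby(_VARIANT_COLS + ["replicate"], sort=False)["score"]
        .min()
        .reset_index()
    )
    agg = per_rep.groupby(_VARIANT_COLS, sort=False)["score"].mean().reset_index()
    per_prot = (
        scores.groupby(_VARIANT_COLS + ["protease"], sort=False)["score"]
        .mean()
        .reset_index()
        .pivot_table(index=_VARIANT_COLS, columns="protease", values="score")
        .add_prefix("score_")
        .reset_index()
    )
    return agg.merge(per_prot, on=_VARIANT_COLS, how="left")


def call_rescues(
    records: pd.DataFrame,
    threshold: float = RESCUE_THRESHOLD,
    wt_label: str = "WT",
) -> pd.DataFrame:
    """Variants whose stability score exceeds the unmutated design's by more
    than ``threshold`` (strictly).

    ``records`` needs columns design_id, site, mutant_aa, score, and one
    row per design with ``mutant_aa == wt_label`` giving the unmutated score.
    A ``wt_aa`` column, if present, triggers mutation-class annotation.
    """
    wt = records[records["mutant_aa"] == wt_label].set_index("design_id")["score"]
    missing = set(records["design_id"]) - set(wt.index)
    if missing:
        raise ValueError(f"no unmutated reference for designs: {sorted(missing)}")
    df = records[records["mutant_aa"] != wt_label].copy()
    df["delta_score"] = df["score"] - df["design_id"].map(wt).astype(float)
    rescues = df[df["delta_score"] > threshold].copy()
    if "wt_aa" in rescues.columns:
        cls = [classify_mutation(w, m) for w, m in zip(rescues["wt_aa"], rescues["mutant_aa"])]
        rescues["polarity_class"] = [c.polarity for c in cls]
        rescues["size_class"] = [c.size for c in cls]
    return rescues.reset_index(drop=True)


def classify_mutation(
    wt_aa: str,
    mut_aa: str,
    nonpolar: frozenset[str] = NONPOLAR_AA,
    sizes: dict[str, int] | None = None,
) -> MutationClass:
    """Polarity-transition and size-transition class of a point mutation.

    Size is measured by sidechain heavy-atom count by default; equal counts
    give 'same'.
    """
    sizes = sizes or SIDECHAIN_HEAVY_ATOMS
    for aa in (wt_aa, mut_aa):
        if aa not in sizes:
            raise ValueError(f"non-canonical amino acid {aa!r}")
    pol = lambda aa: "nonpolar" if aa in nonpolar else "polar"
    polarity = f"{pol(wt_aa)}->{pol(mut_aa)}"
    if sizes[wt_aa] < sizes[mut_aa]:
        size = "small->large"
    elif sizes[wt_aa] > sizes[mut_aa]:
        size = "large->small"
    else:
        size = "same"
    return MutationClass(polarity, size)


def dms_scores(
    counts: pd.DataFrame,
    unfolded_ec50: float | pd.Series,
    hill: float = DEFAULT_HILL,
    rho: float = DEFAULT_DILUTION_RATIO,
    **fit_kwargs,
) -> pd.DataFrame:
    """End-to-end: count table → replicate/protease-aggregated stability scores.

    ``unfolded_ec50`` is the predicted EC50 of the unfolded chain, a constant
    or a per-variant Series indexed like the fit table. The unfolded-state
    predictor itself is an external input to this pipeline.
    """
    fits = fit_ec50_table(counts, hill=hill, rho=rho, **fit_kwargs)
    if isinstance(unfolded_ec50, pd.Series):
        base = fits.set_index(_VARIANT_COLS).index.map(unfolded_ec50)
        fits["score"] = fits["ec50"].to_numpy() - np.asarray(base, dtype=float)
    else:
        fits["score"] = fits["ec50"] - float(unfolded_ec50)
    return aggregate_scores(fits)
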