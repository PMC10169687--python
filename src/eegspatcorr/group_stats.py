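"""Group comparison of M_psi: per-channel-pair one-tailed rank-sum tests,
Benjamini-Hochberg FDR within each region-pair family, significant-pair
counting, and biomarker (channel pair) selection.

A "disruption" is a significant *decrease* of M_psi in the experimental
group relative to control; both one-sided directions are computed so that
increase and decrease maps can be reported side by side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .montage import Montage, region_channel_pairs

__all__ = [
    "GroupComparison",
    "BiomarkerSelection",
    "ranksum_one_tailed",
    "fdr_bh",
    "region_pair_screen",
    "select_biomarker",
]


def ranksum_one_tailed(x, y, direction: str = "less") -> float:
    """One-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``direction='less'`` tests the alternative that ``x`` is stochastically
    smaller than ``y``.  The p-value is computed by exact enumeration when
    the smaller sample has at most 8 observations and there are no ties,
    and by the normal approximation with tie and continuity corrections
    otherwise.  Two completely identical samples are degenerate and return
    p = 0.5 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        warnings.warn("all values identical in both samples; p = 0.5", stacklevel=2)
        return 0.5
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=direction, method=method)
    return float(res.pvalue)


def fdr_bh(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags for one family of tests."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject


@dataclass
class GroupComparison:
    """Channel-pair test results for one (region pair, band, condition) cell."""

    contrast: tuple[str, str]  # (experimental, control)
    carrier_band: str
    envelope_band: str
    condition: str
    region_pair: tuple[str, str]
    pairs: list[tuple[str, str]]
    pvalues_lower: np.ndarray  # per pair, alternative: experimental < control
    pvalues_higher: np.ndarray
    flags_lower: np.ndarray = field(default=None)  # type: ignore[assignment]
    flags_higher: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def frac_lower(self) -> float:
        return float(np.mean(self.flags_lower)) if len(self.pairs) else 0.0

    @property
    def frac_higher(self) -> float:
        return float(np.mean(self.flags_higher)) if len(self.pairs) else 0.0

    @property
    def min_p_lower(self) -> float:
        return float(np.min(self.pvalues_lower))

    @property
    def min_p_higher(self) -> float:
        return float(np.min(self.pvalues_higher))


@dataclass
class BiomarkerSelection:
    """The winning (band, condition, region pair) cell and its best channel pair."""

    found: bool
    carrier_band: str = ""
    envelope_band: str = ""
    condition: str = ""
    region_pair: tuple[str, str] = ("", "")
    channel_pair: tuple[str, str] = ("", "")
    p_value: float = float("nan")
    frac_significant: float = 0.0
    direction: str = "lower"


def _pivot_mpsi(table: pd.DataFrame) -> pd.DataFrame:
    """Index (channel_a, channel_b, carrier_band, condition) x participant -> m_psi."""
    return table.pivot_table(
        index=["channel_a", "channel_b", "carrier_band", "condition"],
        columns="participant",
        values="m_psi",
    )


def region_pair_screen(
    table: pd.DataFrame,
    montage: Montage,
    groups: dict[str, str],
    contrast: tuple[str, str],
    carrier_bands: list[str] | None = None,
    conditions: list[str] | None = None,
    envelope_band: str = "infraslow",
    q: float = 0.05,
    family: str = "region_pair",
) -> list[GroupComparison]:
    """Screen all region pairs x bands x conditions for M_psi disruption.

    ``table`` is a pair-correlation table (see spatcorr), ``groups`` maps
    participant id to group label and ``contrast`` is (experimental, control).
    Within each (region pair, direction) the channel-pair p-values form one
    BH family (``family='global'`` pools all cells per direction instead).
    Returns one :class:`GroupComparison` per cell.
    """
    exp_group, ctrl_group = contrast
    exp_ids = [pid for pid, g in groups.items() if g == exp_group]
    ctrl_ids = [pid for pid, g in groups.items() if g == ctrl_group]
    if len(exp_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"need >= 2 participants per group, got {len(exp_ids)} "
            f"{exp_group!r} and {len(ctrl_ids)} {ctrl_group!r}"
        )

    sub = table[table["envelope_band"] == envelope_band]
    if carrier_bands is None:
        carrier_bands = sorted(sub["carrier_band"].unique())
    if conditions is None:
        conditions = sorted(sub["condition"].unique())
    wide = _pivot_mpsi(sub)

    def values_for(pair, band, condition, ids):
        for key in [(pair[0], pair[1], band, condition), (pair[1], pair[0], band, condition)]:
            if key in wide.index:
                row = wide.loc[key]
                vals = row.reindex(ids)
                if vals.isna().any():
                    missing = [i for i in ids if pd.isna(vals[i])]
                    raise ValueError(
                        f"missing M_psi for participants {missing} at {key}"
                    )
                return vals.to_numpy()
        raise ValueError(f"no M_psi rows for pair {pair}, {band}, {condition}")

    comparisons: list[GroupComparison] = []
    for region_a, region_b in montage.region_pairs():
        pairs = region_channel_pairs(montage, region_a, region_b)
        for band in carrier_bands:
            for condition in conditions:
                p_lo, p_hi = [], []
                for pair in pairs:
                    xv = values_for(pair, band, condition, exp_ids)
                    yv = values_for(pair, band, condition, ctrl_ids)
                    p_lo.append(ranksum_one_tailed(xv, yv, "less"))
                    p_hi.append(ranksum_one_tailed(xv, yv, "greater"))
                comparisons.append(
                    GroupComparison(
                        contrast=contrast,
                        carrier_band=band,
                        envelope_band=envelope_band,
                        condition=condition,
                        region_pair=(region_a, region_b),
                        pairs=pairs,
                        pvalues_lower=np.array(p_lo),
                        pvalues_higher=np.array(p_hi),
                    )
                )

    if family == "region_pair":
        for comp in comparisons:
            comp.flags_lower = fdr_bh(comp.pvalues_lower, q)
            comp.flags_higher = fdr_bh(comp.pvalues_higher, q)
    elif family == "global":
        for attr_p, attr_f in [
            ("pvalues_lower", "flags_lower"),
            ("pvalues_higher", "flags_higher"),
        ]:
            all_p = np.concatenate([getattr(c, attr_p) for c in comparisons])
            all_flags = fdr_bh(all_p, q)
            i = 0
            for c in comparisons:
                k = len(getattr(c, attr_p))
                setattr(c, attr_f, all_flags[i : i + k])
                i += k
    else:
        raise ValueError("family must be 'region_pair' or 'global'")
    return comparisons


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """One summary row per cell and direction (for CSV export / heatmaps)."""
    rows = []
    for c in comparisons:
        for direction in ("lower", "higher"):
            rows.append(
                {
                    "experimental": c.contrast[0],
                    "control": c.contrast[1],
                    "carrier_band": c.carrier_band,
                    "envelope_band": c.envelope_band,
                    "condition": c.condition,
                    "region_a": c.region_pair[0],
                    "region_b": c.region_pair[1],
                    "direction": direction,
                    "n_pairs": len(c.pairs),
                    "n_significant": int(getattr(c, f"flags_{direction}").sum()),
                    "frac_significant": getattr(c, f"frac_{direction}"),
                    "min_p": getattr(c, f"min_p_{direction}"),
                }
            )
    return pd.DataFrame(rows)


def select_biomarker(
    comparisons: list[GroupComparison], direction: str = "lower"
) -> BiomarkerSelection:
    """Pick the biomarker channel pair from a screen.

    The winning cell maximizes the significant-pair fraction (ties broken by
    the smaller minimum uncorrected p, then by cell order); within it, the
    channel pair with the smallest uncorrected p wins.  If no pair is flagged
    anywhere the result has ``found=False``.
    """
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    flagged = [c for c in comparisons if getattr(c, f"flags_{direction}").any()]
    if not flagged:
        return BiomarkerSelection(found=False, direction=direction)
    best = max(
        flagged,
        key=lambda c: (
            getattr(c, f"frac_{direction}"),
            -getattr(c, f"min_p_{direction}"),
        ),
    )
    pvals = getattr(best, f"pvalues_{direction}")
    idx = int(np.argmin(pvals))
    return BiomarkerSelection(
        found=True,
        carrier_band=best.carrier_band,
        envelope_band=best.envelope_band,
        condition=best.condition,
        region_pair=best.region_pair,
        channel_pair=best.pairs[idx],
        p_value=float(pvals[idx]),
        frac_significant=getattr(best, f"frac_{direction}"),
        direction=direction,
    )
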