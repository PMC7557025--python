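"""Correlation screening of variant allele frequencies against fatty-acid
composition, and selection of fatty-acid-associated (FAA) polymorphisms.

Every consensus variant is correlated with each of the five fatty acids
(PAL, STE, OLE, LIO, LIN) using Spearman's rank correlation, separately for
each caller's VAF vector; Kendall's tau-b is reported alongside.  A record
is an FAA polymorphism when |rs| exceeds the cut (default 0.25) with
p < 0.05 under BOTH callers — agreement across callers guards against
caller-specific artifacts.  The relative standard deviation (rStD) of the
VAF vector is reported as a reliability indicator: the wider the VAF spread
across cultivars, the more informative the correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CALLER_BINOMIAL, CALLER_THRESHOLD, ConsensusCall
from .io import FATTY_ACIDS

__all__ = [
    "spearman",
    "kendall",
    "rstd",
    "screen_associations",
    "select_faa",
    "faa_site_count",
    "benjamini_hochberg",
]

_TINY_P = float(np.finfo(float).tiny)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Paired missing values are dropped first; ties get average ranks.  At
    least 5 complete pairs are required.  Zero variance in either vector
    leaves the correlation undefined: returns (nan, nan) with a warning.
    A perfect correlation maps p to the smallest positive float so p stays
    in (0, 1].
    """
    x, y = _paired(x, y)
    if x.size < 5:
        raise ValueError(f"need >= 5 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in spearman input; correlation undefined")
        return float("nan"), float("nan")
    rs, p = stats.spearmanr(x, y)
    p = max(float(p), _TINY_P)
    return float(rs), p


def kendall(x, y) -> tuple[float, float]:
    """Kendall tau-b with tie correction; p by normal approximation."""
    x, y = _paired(x, y)
    if x.size < 5:
        raise ValueError(f"need >= 5 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in kendall input; correlation undefined")
        return float("nan"), float("nan")
    tau, p = stats.kendalltau(x, y, variant="b", method="asymptotic")
    p = max(float(p), _TINY_P)
    return float(tau), p


def rstd(v) -> float:
    """Relative standard deviation: sample sd / mean over defined values.

    Needs at least two defined values and a positive mean; otherwise NaN.
    """
    v = np.asarray(v, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    mean = v.mean()
    if mean <= 0:
        return float("nan")
    return float(v.std(ddof=1) / mean)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (an optional add-on; the default screen uses raw p)."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float), method="bh")


def screen_associations(
    calls: list[ConsensusCall],
    phenotypes: pd.DataFrame,
    include_kendall: bool = True,
    rs_cut: float = 0.25,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Correlate every variant's VAFs with every fatty acid, per caller.

    Returns one row per (variant, fatty acid) — five rows per variant —
    with Spearman rs/p for both callers, optional Kendall tau for the
    threshold caller, the rStD of the threshold-caller VAF vector, and the
    dual-caller ``is_faa`` flag.  Cultivars present in only one of the two
    inputs are dropped (at least five shared cultivars are required).
    """
    if not calls:
        return pd.DataFrame()
    shared = [c for c in calls[0].cultivars if c in phenotypes.index]
    if len(shared) < 5:
        raise ValueError(
            f"only {len(shared)} cultivars shared between calls and phenotypes"
        )
    dropped = sorted(set(calls[0].cultivars) ^ set(phenotypes.index))
    if dropped:
        warnings.warn(f"cultivars missing from one input were dropped: {dropped}")
    pheno = phenotypes.loc[shared]

    rows = []
    for call in calls:
        order = [call.cultivars.index(c) for c in shared]
        vaf_a = call.vaf[CALLER_THRESHOLD][order]
        vaf_b = call.vaf[CALLER_BINOMIAL][order]
        spread = rstd(vaf_a)
        for acid in FATTY_ACIDS:
            y = pheno[acid].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rs_a, p_a = spearman(vaf_a, y)
                rs_b, p_b = spearman(vaf_b, y)
                tau, p_tau = (
                    kendall(vaf_a, y) if include_kendall else (float("nan"),) * 2
                )
            rows.append(
                {
                    "chromosome": call.site.chromosome_id,
                    "position": call.site.position,
                    "ref_allele": call.site.ref_allele,
                    "alt_allele": call.site.alt_allele,
                    "gene": call.gene_id or "",
                    "fatty_acid": acid,
                    "rs_caller_a": rs_a,
                    "p_caller_a": p_a,
                    "rs_caller_b": rs_b,
                    "p_caller_b": p_b,
                    "tau": tau,
                    "p_tau": p_tau,
                    "rstd_vaf": spread,
                }
            )
    records = pd.DataFrame(rows)
    selected = select_faa(records, rs_cut=rs_cut, p_cut=p_cut)
    key_cols = ["chromosome", "position", "ref_allele", "alt_allele", "fatty_acid"]
    selected_keys = set(map(tuple, selected[key_cols].to_numpy()))
    records["is_faa"] = [
        tuple(row) in selected_keys for row in records[key_cols].to_numpy()
    ]
    return records


def select_faa(
    records: pd.DataFrame,
    rs_cut: float = 0.25,
    p_cut: float = 0.05,
    rounding_tol: float = 0.0,
) -> pd.DataFrame:
    """FAA records: |rs| > rs_cut and p < p_cut under BOTH callers.

    The inequality on rs is strict.  ``rounding_tol`` relaxes the rs cut by
    a half-ulp of a table's printed precision (0.005 for two-decimal
    coefficients) so that printed values rounded onto the boundary are
    treated as exceeding it; the default 0.0 applies the exact rule.
    """
    if records.empty:
        return records
    cut = rs_cut - rounding_tol
    keep = (
        (records["rs_caller_a"].abs() > cut)
        & (records["rs_caller_b"].abs() > cut)
        & (records["p_caller_a"] < p_cut)
        & (records["p_caller_b"] < p_cut)
    )
    return records.loc[keep.fillna(False)].copy()


def faa_site_count(selected: pd.DataFrame, gene: str | None = None) -> int:
    """Number of distinct FAA variant sites (optionally within one gene)."""
    if selected.empty:
        return 0
    df = selected if gene is None else selected[selected["gene"] == gene]
    return df[["chromosome", "position", "ref_allele", "alt_allele"]].drop_duplicates().shape[0]
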