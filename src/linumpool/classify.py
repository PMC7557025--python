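"""Two-locus linolenic-acid (LIN) classification of cultivars.

Loss of FAD3 desaturase activity blocks the last desaturation step
(linoleic → linolenic), so cultivars carrying BOTH a FAD3A nonsense variant
and the FAD3B His→Tyr missense variant are low-LIN, cultivars carrying
exactly one are mid-LIN, and cultivars carrying neither are high-LIN.  One
exception pattern is generalized into the rule: a cultivar carrying any
OTHER high-frequency FAD3A nonsense variant is also called low-LIN, with an
explicit exception flag (in the emulated panel a single line owed its low
LIN to an alternative Arg→stop variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import datasets
from .calling import ConsensusCall
from .genemodel import CodonEffect, GenomicSite

__all__ = [
    "ClassBounds",
    "ConfigurationError",
    "presence",
    "classify_lin",
    "evaluate_classifier",
]

DEFAULT_PRESENCE_FLOOR = 0.40

LIN_CLASSES = ("low", "mid", "high")


class ConfigurationError(ValueError):
    """Key variant sites absent from the call set."""


@dataclass(frozen=True)
class ClassBounds:
    """Phenotype-derived LIN class bounds, percent of oil.

    Between low_max and mid, and between mid and high_min, lie gaps: a
    cultivar whose LIN falls there is left unclassified rather than forced
    into a class.
    """

    low_max: float = 10.0
    mid_range: tuple[float, float] = (30.0, 47.0)
    high_min: float = 50.0

    def classify(self, lin_pct: float) -> str:
        if lin_pct <= self.low_max:
            return "low"
        if self.mid_range[0] <= lin_pct <= self.mid_range[1]:
            return "mid"
        if lin_pct >= self.high_min:
            return "high"
        return "unclassified"


def presence(vaf: float, presence_floor: float = DEFAULT_PRESENCE_FLOOR) -> bool:
    """A variant is present in a pool when its VAF reaches the floor.

    Missing VAFs (NaN) are absence of evidence and count as not present.
    """
    if not 0 < presence_floor < 1:
        raise ValueError("presence_floor must be in (0, 1)")
    if vaf is None or np.isnan(vaf):
        return False
    return vaf >= presence_floor


def _mean_vaf_at(calls: list[ConsensusCall], site: GenomicSite) -> np.ndarray | None:
    for call in calls:
        if call.site.key == site.key:
            return call.mean_vaf()
    return None


def classify_lin(
    calls: list[ConsensusCall],
    annotations: list[tuple[GenomicSite, str | None, str, CodonEffect | None]],
    presence_floor: float = DEFAULT_PRESENCE_FLOOR,
    fad3a_key: GenomicSite = datasets.KEY_FAD3A_NONSENSE,
    fad3b_key: GenomicSite = datasets.KEY_FAD3B_MISSENSE,
) -> pd.DataFrame:
    """Per-cultivar LIN class from the two key variants' VAFs.

    ``annotations`` (as produced by :func:`linumpool.genemodel.annotate_sites`)
    identify any additional FAD3A nonsense variants; a cultivar where one of
    those reaches the presence floor is overridden to low with
    ``exception_flag`` set.  Raises :class:`ConfigurationError` when a key
    site is missing from the call set.
    """
    missing = []
    fa_vaf = _mean_vaf_at(calls, fad3a_key)
    if fa_vaf is None:
        missing.append(f"FAD3A key site {fad3a_key.chromosome_id}:{fad3a_key.position}")
    fb_vaf = _mean_vaf_at(calls, fad3b_key)
    if fb_vaf is None:
        missing.append(f"FAD3B key site {fad3b_key.chromosome_id}:{fad3b_key.position}")
    if missing:
        raise ConfigurationError("key sites absent from call set: " + "; ".join(missing))

    cultivars = calls[0].cultivars
    n = len(cultivars)

    # max VAF over any other FAD3A nonsense variant present in the calls
    alt_nonsense_sites = {
        site.key
        for site, gene_id, _loc, effect in annotations
        if gene_id == "FAD3A" and effect is not None and effect.is_nonsense
        and site.key != fad3a_key.key
    }
    alt_vaf = np.zeros(n)
    any_alt = False
    for call in calls:
        if call.site.key in alt_nonsense_sites:
            any_alt = True
            alt_vaf = np.fmax(alt_vaf, np.nan_to_num(call.mean_vaf(), nan=0.0))
    if not any_alt:
        alt_vaf = np.zeros(n)

    rows = []
    for j, cultivar in enumerate(cultivars):
        fa = float(fa_vaf[j])
        fb = float(fb_vaf[j])
        falt = float(alt_vaf[j])
        has_a = presence(fa, presence_floor)
        has_b = presence(fb, presence_floor)
        has_alt = presence(falt, presence_floor)
        if has_a and has_b:
            lin_class, exception = "low", False
        elif has_alt:
            lin_class, exception = "low", True
        elif has_a or has_b:
            lin_class, exception = "mid", False
        else:
            lin_class, exception = "high", False
        rows.append(
            {
                "cultivar": cultivar,
                "fad3a_key_vaf": fa,
                "fad3b_key_vaf": fb,
                "alt_nonsense_vaf": falt,
                "fad3a_present": has_a,
                "fad3b_present": has_b,
                "alt_nonsense_present": has_alt,
                "lin_class": lin_class,
                "exception_flag": exception,
            }
        )
    return pd.DataFrame(rows).set_index("cultivar")


def evaluate_classifier(
    results: pd.DataFrame,
    phenotypes: pd.DataFrame,
    bounds: ClassBounds = ClassBounds(),
) -> dict:
    """Compare genotype-derived classes against phenotype-derived classes.

    Returns the merged table, a confusion matrix (genotype rows × phenotype
    columns, unclassified kept separate) and the accuracy over cultivars
    whose LIN percentage falls inside one of the class bounds.
    """
    merged = results.join(phenotypes["LIN"], how="inner")
    merged["phenotype_class"] = merged["LIN"].map(bounds.classify)
    merged["concordant"] = merged["lin_class"] == merged["phenotype_class"]

    confusion = pd.crosstab(
        merged["lin_class"], merged["phenotype_class"], dropna=False
    )
    classified = merged[merged["phenotype_class"] != "unclassified"]
    accuracy = (
        float(classified["concordant"].mean()) if len(classified) else float("nan")
    )
    return {
        "table": merged,
        "confusion": confusion,
        "accuracy": accuracy,
        "n_unclassified": int((merged["phenotype_class"] == "unclassified").sum()),
    }
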