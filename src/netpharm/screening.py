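"""Pre-network filters: rule-of-five drug-likeness on compounds, a
minimum-support filter on targets, and removal of compounds left without
any target.

Boundary semantics follow the rule-of-five criteria as commonly printed: molecular weight
strictly below 500 g/mol; H-bond donors <= 5; H-bond acceptors <= 10;
MlogP <= 5. A target is kept iff at least ``min_support`` distinct compounds
interact with it (default 5, i.e. "fewer than five" removed).

Every filter returns a :class:`ScreeningResult` that partitions its input:
kept + rejected = input, and each rejected item carries the flags naming the
criteria it failed. Filters are idempotent and insensitive to row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: rule-of-five bounds (name -> (column, predicate description))
MW_MAX = 500.0
HBD_MAX = 5
HBA_MAX = 10
MLOGP_MAX = 5.0

LIPINSKI_FLAGS = ("mw", "hbd", "hba", "mlogp")


@dataclass
class ScreeningResult:
    """Outcome of one filter: a disjoint kept/rejected partition of the input
    plus, per rejected item, the list of failed criteria."""

    kept: pd.DataFrame
    rejected: pd.DataFrame
    flags: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    @property
    def n_input(self) -> int:
        return self.n_kept + self.n_rejected


def lipinski_filter(compounds: pd.DataFrame) -> ScreeningResult:
    """Apply the four printed rule-of-five criteria to a compound table.

    Kept iff ``mw < 500 and hbd <= 5 and hba <= 10 and mlogp <= 5``; the
    molecular-weight bound is strict, the others inclusive. Raises
    :class:`ValidationError` naming compound and field when a property is
    missing or non-numeric.
    """
    for col in ("mw", "hbd", "hba", "mlogp"):
        if col not in compounds.columns:
            raise ValidationError(f"compound table lacks required column {col!r}")
        series = pd.to_numeric(compounds[col], errors="coerce")
        if series.isna().any():
            bad = compounds.loc[series.isna(), "compound_id"].tolist()
            raise ValidationError(
                f"missing or non-numeric {col!r} for compound(s) {bad}")

    fails = {
        "mw": ~(compounds["mw"] < MW_MAX),
        "hbd": ~(compounds["hbd"] <= HBD_MAX),
        "hba": ~(compounds["hba"] <= HBA_MAX),
        "mlogp": ~(compounds["mlogp"] <= MLOGP_MAX),
    }
    any_fail = fails["mw"] | fails["hbd"] | fails["hba"] | fails["mlogp"]
    flags = {}
    for idx in compounds.index[any_fail]:
        cid = compounds.at[idx, "compound_id"]
        flags[cid] = [name for name in LIPINSKI_FLAGS if bool(fails[name].at[idx])]
    kept = compounds[~any_fail].reset_index(drop=True)
    rejected = compounds[any_fail].reset_index(drop=True)
    logger.info("lipinski_filter: kept %d / rejected %d of %d compounds",
                len(kept), len(rejected), len(compounds))
    return ScreeningResult(kept, rejected, flags)


def filter_targets_by_support(interactions: pd.DataFrame,
                              min_support: int = 5) -> ScreeningResult:
    """Keep a target iff at least ``min_support`` distinct compounds interact
    with it; all rows of removed targets go to the rejected partition."""
    if min_support < 1:
        raise ValidationError(f"min_support must be >= 1, got {min_support}")
    if interactions.empty:
        return ScreeningResult(interactions.copy(), interactions.iloc[0:0].copy(), {})
    support = interactions.groupby("target_id")["compound_id"].nunique()
    low = set(support.index[support < min_support])
    mask = interactions["target_id"].isin(low)
    kept = interactions[~mask].reset_index(drop=True)
    rejected = interactions[mask].reset_index(drop=True)
    flags = {tid: [f"support<{min_support}"] for tid in sorted(low)}
    logger.info("filter_targets_by_support(min_support=%d): kept %d / rejected %d rows "
                "(%d targets removed)", min_support, len(kept), len(rejected), len(low))
    return ScreeningResult(kept, rejected, flags)


def drop_targetless_compounds(interactions: pd.DataFrame,
                              compounds: pd.DataFrame) -> ScreeningResult:
    """Keep the compounds that retain at least one interaction row."""
    with_targets = set(interactions["compound_id"]) if len(interactions) else set()
    mask = compounds["compound_id"].isin(with_targets)
    kept = compounds[mask].reset_index(drop=True)
    rejected = compounds[~mask].reset_index(drop=True)
    flags = {cid: ["no_targets"] for cid in rejected["compound_id"]}
    logger.info("drop_targetless_compounds: kept %d / rejected %d of %d compounds",
                len(kept), len(rejected), len(compounds))
    return ScreeningResult(kept, rejected, flags)


def screen(compounds: pd.DataFrame, interactions: pd.DataFrame,
           min_support: int = 5, apply_lipinski: bool = True
           ) -> dict[str, ScreeningResult | pd.DataFrame]:
    """Run the default screening cascade.

    Order: rule-of-five on compounds -> restrict interactions to drug-like
    compounds -> target-support filter -> drop compounds left targetless.
    Returns the three stage results plus the final screened tables.
    """
    if apply_lipinski:
        lip = lipinski_filter(compounds)
    else:
        lip = ScreeningResult(compounds.copy(), compounds.iloc[0:0].copy(), {})
    druglike_ids = set(lip.kept["compound_id"])
    inter = interactions[interactions["compound_id"].isin(druglike_ids)]
    inter = inter.reset_index(drop=True)
    support = filter_targets_by_support(inter, min_support=min_support)
    final = drop_targetless_compounds(support.kept, lip.kept)
    return {
        "lipinski": lip,
        "support": support,
        "targetless": final,
        "compounds": final.kept,
        "interactions": support.kept,
    }
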