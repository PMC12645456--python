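"""MAG-OTU community tables: singleton filtering, turnover and guild sums.

The community table is OTU × sampling day, entries are relative abundance
as percent of binned (MAG-mapped) reads. Per-OTU annotations — autotrophy,
hydrogenase gene counts, taxonomy — arrive as metadata; no sequence
annotation happens here. "Detected" means relative abundance > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "TurnoverSummary",
    "drop_single_date_otus",
    "richness_and_shared",
    "guild_abundance",
]


@dataclass
class OtuTable:
    """OTU × sample-day relative abundances (percent) with per-OTU annotations.

    ``abundance``: DataFrame indexed by OTU id, one column per Julian day.
    ``annotations``: DataFrame indexed by OTU id; conventional columns are
    ``autotroph`` (bool), ``nife_hydrogenases`` / ``fefe_hydrogenases``
    (int counts) and ``taxonomy`` (str), but any boolean/numeric column can
    drive a guild sum.
    """

    abundance: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("relative abundances must be >= 0")
        if (self.abundance.sum(axis=0) > 100 + 1e-9).any():
            raise ValueError("per-sample abundance sums exceed 100%")
        if self.annotations is not None:
            missing = set(self.abundance.index) - set(self.annotations.index)
            if missing:
                raise ValueError(f"annotations missing for OTUs: {sorted(missing)[:5]} ...")

    @property
    def otu_ids(self):
        return list(self.abundance.index)

    @property
    def sample_days(self):
        return list(self.abundance.columns)


@dataclass(frozen=True)
class TurnoverSummary:
    """Per-day OTU richness and the count shared across every sampling date."""

    richness: dict
    n_shared_all_days: int
    richness_after_filter: dict | None = None

    def __post_init__(self):
        if self.n_shared_all_days > min(self.richness.values()):
            raise ValueError("shared count cannot exceed minimum richness")


def drop_single_date_otus(table: OtuTable) -> tuple[OtuTable, pd.Series]:
    """Remove OTUs detected on exactly one sampling date.

    Returns the filtered table and the per-day retained fraction (percent of
    the original per-day total abundance carried by the surviving OTUs; the
    study retained 91–99%).
    """
    if table.abundance.shape[1] < 2:
        raise ValueError("need at least 2 sampling days")
    present = table.abundance > 0
    keep = present.sum(axis=1) != 1
    before = table.abundance.sum(axis=0)
    filtered = table.abundance.loc[keep]
    after = filtered.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        retained = (100.0 * after / before).where(before > 0, 100.0)
    ann = table.annotations.loc[keep] if table.annotations is not None else None
    return OtuTable(abundance=filtered, annotations=ann), retained


def richness_and_shared(table: OtuTable) -> TurnoverSummary:
    """Per-day richness (OTUs with abundance > 0) and the all-dates core count.

    Richness is reported on the table as given (headline numbers predate
    singleton filtering); the post-filter richness is attached alongside.
    """
    present = table.abundance > 0
    richness = {day: int(present[day].sum()) for day in table.sample_days}
    shared = int(present.all(axis=1).sum())
    filtered, _ = drop_single_date_otus(table)
    present_f = filtered.abundance > 0
    richness_f = {day: int(present_f[day].sum()) for day in filtered.sample_days}
    return TurnoverSummary(
        richness=richness, n_shared_all_days=shared, richness_after_filter=richness_f
    )


def guild_abundance(table: OtuTable, flag) -> pd.Series:
    """Per-day summed relative abundance over OTUs satisfying a predicate.

    ``flag`` is either an annotation column name (boolean, or numeric —
    nonzero counts as in-guild, so hydrogenase gene counts work directly) or
    a callable applied to each annotation row. Example guilds: putative
    autotrophs; autotrophs that encode [NiFe]-/[FeFe]-hydrogenases.
    """
    if table.annotations is None:
        raise ValueError("table has no annotations")
    ann = table.annotations.loc[table.abundance.index]
    if callable(flag):
        mask = ann.apply(flag, axis=1).astype(bool)
    else:
        if flag not in ann.columns:
            raise KeyError(
                f"unknown annotation {flag!r}; available: {list(ann.columns)}"
            )
        mask = ann[flag].astype(bool)
    return table.abundance.loc[mask.to_numpy()].sum(axis=0)
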