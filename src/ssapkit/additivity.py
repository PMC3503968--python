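"""Additivity-deviation scoring of polyploid marker profiles.

In an allopolyploid, the expected ("additive") band profile is the union
of the band sets of its two diploid progenitor taxa.  Each band in each
polyploid taxon is scored against this prediction:

* ``additive_present`` — a parental band present in the polyploid;
* ``missing``          — a parental band absent from the polyploid;
* ``new``              — a band absent from both diploids but present in
                         the polyploid;
* ``absent_everywhere`` — a band carried by neither side.

Non-additive bands are further partitioned into *sharing categories*:
the subset of polyploid taxa in which the band is new (resp. missing).
With three polyploid taxa this gives the familiar 7-way layout (all
three, each pair, each singleton).  Lost parental bands that were
specific to one progenitor are attributed to that parent, yielding a
paternal fraction of losses per polyploid taxon.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .marker_data import MarkerMatrix, TaxonScheme, ValidationError, taxon_presence

__all__ = [
    "PARENTAL_STATUSES",
    "POLYPLOID_LABELS",
    "BandClassification",
    "DeviationBlock",
    "AdditivitySummary",
    "classify_parental_bands",
    "score_polyploid_deviation",
    "partition_sharing_categories",
    "parental_origin_of_losses",
    "deviation_summary",
    "category_label",
    "sharing_categories",
]

PARENTAL_STATUSES = (
    "shared_parental", "maternal_specific", "paternal_specific", "absent_in_parents",
)
POLYPLOID_LABELS = ("additive_present", "missing", "new", "absent_everywhere")


def category_label(subset: frozenset[str], polyploids: Iterable[str]) -> str:
    """Canonical '+'-joined label of a polyploid subset, in scheme order."""
    return "+".join(t for t in polyploids if t in subset)


def sharing_categories(polyploids: tuple[str, ...]) -> list[str]:
    """All 2^k - 1 non-empty subsets, largest first, in scheme order.

    For the three-taxon layout this yields the printed column order:
    all three, the three pairs, the three singletons.
    """
    k = len(polyploids)
    subsets = []
    for size in range(k, 0, -1):
        from itertools import combinations
        for combo in combinations(polyploids, size):
            subsets.append("+".join(combo))
    return subsets


@dataclass(frozen=True)
class BandClassification:
    """Per-locus parental status and per-polyploid deviation labels."""

    te_family: str
    parental_status: pd.Series          # locus -> status
    polyploid_presence: pd.DataFrame    # locus x polyploid (bool)
    labels: pd.DataFrame | None         # locus x polyploid (label), None until scored
    polyploids: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.parental_status.unique()) - set(PARENTAL_STATUSES)
        if bad:
            raise ValidationError(f"invalid parental statuses {bad}")
        if self.labels is not None:
            if not self.labels.index.equals(self.parental_status.index):
                raise ValidationError("labels index mismatch")
            bad = set(np.unique(self.labels.to_numpy())) - set(POLYPLOID_LABELS)
            if bad:
                raise ValidationError(f"invalid polyploid labels {bad}")

    @property
    def parental_total(self) -> int:
        return int((self.parental_status != "absent_in_parents").sum())

    def parental_counts(self) -> dict[str, int]:
        vc = self.parental_status.value_counts()
        return {
            "total": self.parental_total,
            "shared": int(vc.get("shared_parental", 0)),
            "maternal_specific": int(vc.get("maternal_specific", 0)),
            "paternal_specific": int(vc.get("paternal_specific", 0)),
        }


def classify_parental_bands(m: MarkerMatrix, s: TaxonScheme) -> BandClassification:
    """Assign each locus a parental status from diploid taxon-level presence."""
    pres = taxon_presence(m, s)
    mat = pres.loc[s.maternal_diploid].to_numpy()
    pat = pres.loc[s.paternal_diploid].to_numpy()
    status = np.where(
        mat & pat, "shared_parental",
        np.where(mat, "maternal_specific",
                 np.where(pat, "paternal_specific", "absent_in_parents")),
    )
    poly = pres.loc[list(s.polyploids)].T  # locus x polyploid
    return BandClassification(
        te_family=m.te_family,
        parental_status=pd.Series(status, index=list(m.locus_ids)),
        polyploid_presence=poly,
        labels=None,
        polyploids=s.polyploids,
    )


def score_polyploid_deviation(c: BandClassification) -> BandClassification:
    """Label each (locus, polyploid) pair against the predicted additive profile."""
    in_parents = (c.parental_status != "absent_in_parents").to_numpy()
    labels = {}
    for t in c.polyploids:
        present = c.polyploid_presence[t].to_numpy().astype(bool)
        labels[t] = np.where(
            in_parents & present, "additive_present",
            np.where(in_parents, "missing",
                     np.where(present, "new", "absent_everywhere")),
        )
    return BandClassification(
        te_family=c.te_family,
        parental_status=c.parental_status,
        polyploid_presence=c.polyploid_presence,
        labels=pd.DataFrame(labels, index=c.parental_status.index),
        polyploids=c.polyploids,
    )


def _require_labels(c: BandClassification) -> pd.DataFrame:
    if c.labels is None:
        raise ValidationError("polyploid labels not scored yet; "
                              "run score_polyploid_deviation first")
    return c.labels


def partition_sharing_categories(
    c: BandClassification, block: Literal["new", "lost"]
) -> dict[str, int]:
    """Count non-additive bands by the subset of polyploid taxa carrying them.

    ``block='new'`` partitions gained bands by where they are new;
    ``block='lost'`` partitions parental bands by where they are missing.
    Every non-additive band lands in exactly one of the 2^k - 1 non-empty
    subsets.
    """
    labels = _require_labels(c)
    if block not in ("new", "lost"):
        raise ValidationError(f"invalid block {block!r}")
    target = "new" if block == "new" else "missing"
    counts = {cat: 0 for cat in sharing_categories(c.polyploids)}
    hit = labels.eq(target)
    any_hit = hit.any(axis=1)
    for _, row in hit[any_hit].iterrows():
        subset = frozenset(t for t in c.polyploids if row[t])
        counts[category_label(subset, c.polyploids)] += 1
    return counts


@dataclass(frozen=True)
class LossOrigin:
    """Parental attribution of bands lost in one polyploid taxon."""

    taxon: str
    paternal_lost: int
    maternal_lost: int
    shared_lost: int          # shared-parental losses: origin unattributable
    fraction_paternal: float | None   # None when no attributable losses

    @property
    def attributable(self) -> int:
        return self.paternal_lost + self.maternal_lost


def parental_origin_of_losses(c: BandClassification, taxon: str) -> LossOrigin:
    """Among bands missing in ``taxon``, attribute progenitor-specific ones.

    Shared-parental losses cannot be assigned to either parent and are
    counted separately; the paternal fraction is computed over the
    attributable (progenitor-specific) losses only.
    """
    labels = _require_labels(c)
    if taxon not in c.polyploids:
        raise ValidationError(f"{taxon!r} is not a polyploid taxon")
    missing = labels[taxon] == "missing"
    status = c.parental_status[missing]
    pat = int((status == "paternal_specific").sum())
    mat = int((status == "maternal_specific").sum())
    shared = int((status == "shared_parental").sum())
    frac = pat / (pat + mat) if (pat + mat) > 0 else None
    return LossOrigin(taxon=taxon, paternal_lost=pat, maternal_lost=mat,
                      shared_lost=shared, fraction_paternal=frac)


@dataclass(frozen=True)
class DeviationBlock:
    """One Table-5-shaped block (new or lost bands) for a single TE family.

    Percentages follow the printed conventions: the "in all" percentage is
    relative to the parental band total in both blocks; per-taxon
    percentages are relative to the block's "in all" count for new bands
    but to the parental total for lost bands; category percentages are
    always relative to the block's "in all" count.
    """

    block: str                       # 'new' | 'lost'
    in_all: int
    per_taxon: dict[str, int]
    categories: dict[str, int]
    parental_total: int

    def __post_init__(self) -> None:
        if sum(self.categories.values()) != self.in_all:
            raise ValidationError(f"{self.block}: categories do not sum to in_all")
        for taxon, n in self.per_taxon.items():
            tot = sum(v for cat, v in self.categories.items()
                      if taxon in cat.split("+"))
            if tot != n:
                raise ValidationError(
                    f"{self.block}: {taxon} count {n} != category sum {tot}")
        if self.block == "lost" and self.in_all > self.parental_total:
            raise ValidationError("more lost bands than parental bands")

    def _pct(self, num: int, den: int) -> float | None:
        return 100 * num / den if den else None

    def in_all_pct(self) -> float | None:
        return self._pct(self.in_all, self.parental_total)

    def per_taxon_pct(self, taxon: str) -> float | None:
        den = self.in_all if self.block == "new" else self.parental_total
        return self._pct(self.per_taxon[taxon], den)

    def category_pct(self, cat: str) -> float | None:
        return self._pct(self.categories[cat], self.in_all)


@dataclass(frozen=True)
class AdditivitySummary:
    """All per-TE counts/proportions of the additivity analysis."""

    te_family: str
    parental: dict[str, int]
    new: DeviationBlock
    lost: DeviationBlock
    new_missing_ratio: dict[str, float | None]
    loss_origin: dict[str, LossOrigin]
    deviation_proportion: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Table-5-shaped two-row frame (new and lost blocks)."""
        rows = []
        for blk in (self.new, self.lost):
            row: dict[str, object] = {
                "te_family": self.te_family,
                "block": blk.block,
                "in_all": blk.in_all,
                "in_all_pct": blk.in_all_pct(),
            }
            for t, n in blk.per_taxon.items():
                row[f"in_{t}"] = n
                row[f"in_{t}_pct"] = blk.per_taxon_pct(t)
            for cat, n in blk.categories.items():
                row[cat] = n
                row[f"{cat}_pct"] = blk.category_pct(cat)
            rows.append(row)
        return pd.DataFrame(rows)


def deviation_summary(c: BandClassification) -> AdditivitySummary:
    """Assemble the full per-TE additivity summary from scored labels.

    The per-taxon *deviation proportion* is defined as
    (new + missing) / (parental total + new) for that taxon — the share
    of bands relevant to the taxon that depart from additivity.
    """
    labels = _require_labels(c)
    parental = c.parental_counts()
    blocks = {}
    for block in ("new", "lost"):
        target = "new" if block == "new" else "missing"
        cats = partition_sharing_categories(c, block)
        per_taxon = {t: int((labels[t] == target).sum()) for t in c.polyploids}
        blocks[block] = DeviationBlock(
            block=block,
            in_all=sum(cats.values()),
            per_taxon=per_taxon,
            categories=cats,
            parental_total=parental["total"],
        )
    ratio = {}
    dev_prop = {}
    for t in c.polyploids:
        new_t = blocks["new"].per_taxon[t]
        miss_t = blocks["lost"].per_taxon[t]
        ratio[t] = new_t / miss_t if miss_t else None
        denom = parental["total"] + new_t
        dev_prop[t] = (new_t + miss_t) / denom if denom else 0.0
    origins = {t: parental_origin_of_losses(c, t) for t in c.polyploids}
    return AdditivitySummary(
        te_family=c.te_family,
        parental=parental,
        new=blocks["new"],
        lost=blocks["lost"],
        new_missing_ratio=ratio,
        loss_origin=origins,
        deviation_proportion=dev_prop,
    )
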