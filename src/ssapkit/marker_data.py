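"""Data model and I/O for dominant presence/absence marker matrices.

An SSAP (or AFLP-like) experiment yields, for each transposable-element
family, a binary matrix of band calls: rows are loci (scored fragments),
columns are accessions, cells are 1 (band present) or 0 (absent).  A
:class:`TaxonScheme` assigns accessions to taxa and names the two diploid
progenitor taxa (maternal and paternal) and the polyploid taxa derived
from them.

The module also packages a transcription of the study's printed count
tables (parental band distribution, additivity-deviation blocks) so that
every derivable statistic can be recomputed without the undeposited raw
matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "TaxonScheme",
    "CountFixture",
    "MatrixParseError",
    "ValidationError",
    "read_matrix",
    "write_matrix",
    "read_taxon_scheme",
    "write_taxon_scheme",
    "taxon_presence",
    "load_paper_fixture",
    "FIXTURE_IDS",
]

FIXTURE_IDS = ("table3", "table4", "table5_new", "table5_lost")


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


class MatrixParseError(ValueError):
    """A marker-matrix file could not be parsed as a binary table."""


@dataclass(frozen=True)
class MarkerMatrix:
    """Binary loci × accessions presence calls for one TE family.

    Parameters
    ----------
    te_family
        Label of the transposable-element family the bands derive from.
    locus_ids, accession_ids
        Ordered, duplicate-free row and column labels.
    calls
        ``(n_loci, n_accessions)`` array of 0/1 presence calls; no
        missing cells are permitted (dominant scoring is total).
    """

    te_family: str
    locus_ids: tuple[str, ...]
    accession_ids: tuple[str, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        locus_ids = tuple(str(x) for x in self.locus_ids)
        accession_ids = tuple(str(x) for x in self.accession_ids)
        calls = np.asarray(self.calls)
        if calls.ndim != 2:
            raise ValidationError("calls must be a 2-D array")
        if calls.shape != (len(locus_ids), len(accession_ids)):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(locus_ids)} loci x {len(accession_ids)} accessions"
            )
        if len(locus_ids) < 1:
            raise ValidationError("need at least 1 locus")
        if len(accession_ids) < 2:
            raise ValidationError("need at least 2 accessions")
        if len(set(locus_ids)) != len(locus_ids):
            raise ValidationError("duplicate locus ids")
        if len(set(accession_ids)) != len(accession_ids):
            raise ValidationError("duplicate accession ids")
        if not np.isin(calls, (0, 1)).all():
            bad = np.argwhere(~np.isin(calls, (0, 1)))[0]
            raise ValidationError(
                f"non-binary call {calls[bad[0], bad[1]]!r} at locus "
                f"{locus_ids[bad[0]]!r}, accession {accession_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "locus_ids", locus_ids)
        object.__setattr__(self, "accession_ids", accession_ids)
        object.__setattr__(self, "calls", calls.astype(np.uint8))
        self.calls.setflags(write=False)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def empty_loci(self) -> tuple[str, ...]:
        """Loci absent in every accession (retained but flagged)."""
        mask = self.calls.sum(axis=1) == 0
        return tuple(l for l, m in zip(self.locus_ids, mask) if m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls.copy(), index=list(self.locus_ids),
            columns=list(self.accession_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, te_family: str) -> "MarkerMatrix":
        return cls(
            te_family=te_family,
            locus_ids=tuple(str(i) for i in frame.index),
            accession_ids=tuple(str(c) for c in frame.columns),
            calls=frame.to_numpy(),
        )

    def subset_accessions(self, accessions: Sequence[str]) -> "MarkerMatrix":
        idx = [self.accession_ids.index(a) for a in accessions]
        return MarkerMatrix(
            te_family=self.te_family,
            locus_ids=self.locus_ids,
            accession_ids=tuple(accessions),
            calls=self.calls[:, idx],
        )


@dataclass(frozen=True)
class TaxonScheme:
    """Accession→taxon map with progenitor and polyploid roles.

    ``maternal_diploid`` and ``paternal_diploid`` name the two diploid
    progenitor taxa; ``polyploids`` lists the derived allopolyploid taxa
    in a fixed rendering order.
    """

    taxon_of: Mapping[str, str]
    maternal_diploid: str
    paternal_diploid: str
    polyploids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_of", dict(self.taxon_of))
        object.__setattr__(self, "polyploids", tuple(self.polyploids))
        if self.maternal_diploid == self.paternal_diploid:
            raise ValidationError("maternal and paternal taxa must differ")
        if set(self.polyploids) & {self.maternal_diploid, self.paternal_diploid}:
            raise ValidationError("polyploids must be disjoint from diploids")
        if len(set(self.polyploids)) != len(self.polyploids):
            raise ValidationError("duplicate polyploid taxon")
        present = set(self.taxon_of.values())
        for t in (self.maternal_diploid, self.paternal_diploid, *self.polyploids):
            if t not in present:
                raise ValidationError(f"taxon {t!r} has no accession")

    @property
    def taxa(self) -> tuple[str, ...]:
        return (self.maternal_diploid, self.paternal_diploid, *self.polyploids)

    def accessions_of(self, taxon: str) -> tuple[str, ...]:
        return tuple(a for a, t in self.taxon_of.items() if t == taxon)

    def check_matrix(self, m: MarkerMatrix) -> None:
        missing = [a for a in m.accession_ids if a not in self.taxon_of]
        if missing:
            raise ValidationError(f"unmapped accessions: {missing}")


def read_matrix(path: str | Path, te_family: str) -> MarkerMatrix:
    """Read a tab-separated binary marker table (loci rows, accession columns).

    '#'-prefixed lines are comments.  Cells must be 0 or 1; anything else
    raises :class:`MatrixParseError` naming the offending locus/accession.
    """
    path = Path(path)
    rows: list[tuple[str, list[str]]] = []
    header: list[str] | None = None
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields[1:]]
                continue
            rows.append((fields[0].strip(), [f.strip() for f in fields[1:]]))
    if header is None or not rows:
        raise ValidationError(f"{path}: empty marker table")
    calls = np.zeros((len(rows), len(header)), dtype=np.uint8)
    for i, (locus, vals) in enumerate(rows):
        if len(vals) != len(header):
            raise MatrixParseError(
                f"{path}: row {locus!r} has {len(vals)} cells, expected {len(header)}"
            )
        for j, v in enumerate(vals):
            if v == "0":
                calls[i, j] = 0
            elif v == "1":
                calls[i, j] = 1
            else:
                raise MatrixParseError(
                    f"{path}: non-binary cell {v!r} at locus {locus!r}, "
                    f"accession {header[j]!r}"
                )
    return MarkerMatrix(
        te_family=te_family,
        locus_ids=tuple(r[0] for r in rows),
        accession_ids=tuple(header),
        calls=calls,
    )


def write_matrix(m: MarkerMatrix, path: str | Path) -> None:
    """Write the tab-separated dialect accepted by :func:`read_matrix`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# te_family: {m.te_family}\n")
        fh.write("locus\t" + "\t".join(m.accession_ids) + "\n")
        for locus, row in zip(m.locus_ids, m.calls):
            fh.write(locus + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_taxon_scheme(s: TaxonScheme, path: str | Path) -> None:
    """Write a two-column accession/taxon TSV with role directives in the header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# maternal_diploid: {s.maternal_diploid}\n")
        fh.write(f"# paternal_diploid: {s.paternal_diploid}\n")
        fh.write(f"# polyploids: {','.join(s.polyploids)}\n")
        fh.write("accession\ttaxon\n")
        for a, t in s.taxon_of.items():
            fh.write(f"{a}\t{t}\n")


def read_taxon_scheme(path: str | Path) -> TaxonScheme:
    path = Path(path)
    roles: dict[str, str] = {}
    taxon_of: dict[str, str] = {}
    header_seen = False
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip("# ").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    roles[k.strip()] = v.strip()
                continue
            if not header_seen:
                header_seen = True
                continue
            acc, taxon = line.split("\t")[:2]
            taxon_of[acc.strip()] = taxon.strip()
    for key in ("maternal_diploid", "paternal_diploid", "polyploids"):
        if key not in roles:
            raise ValidationError(f"{path}: missing '# {key}:' directive")
    return TaxonScheme(
        taxon_of=taxon_of,
        maternal_diploid=roles["maternal_diploid"],
        paternal_diploid=roles["paternal_diploid"],
        polyploids=tuple(t.strip() for t in roles["polyploids"].split(",") if t.strip()),
    )


def taxon_presence(m: MarkerMatrix, s: TaxonScheme) -> pd.DataFrame:
    """Taxon-level presence: a band is present in a taxon iff at least one
    of its accessions carries it.

    Returns a boolean DataFrame indexed by taxon with one column per locus.
    """
    s.check_matrix(m)
    out = {}
    for taxon in s.taxa:
        idx = [m.accession_ids.index(a) for a in m.accession_ids
               if s.taxon_of[a] == taxon]
        out[taxon] = m.calls[:, idx].any(axis=1)
    return pd.DataFrame(out, index=list(m.locus_ids)).T


# ---------------------------------------------------------------------------
# Packaged transcriptions of the study's printed count tables


@dataclass(frozen=True)
class CountFixture:
    """Printed per-TE counts (and printed percentages) for one table.

    ``records`` maps TE family → the raw transcription; structure depends
    on ``table_id``:

    * ``table3`` — total, shared, maternal-specific, paternal-specific
      counts with printed percentages;
    * ``table4`` — deviation proportions with 95% CI bounds per polyploid;
    * ``table5_new`` / ``table5_lost`` — "in all" count, three per-taxon
      counts and the 7 sharing-category counts, all with printed
      percentages.
    """

    table_id: str
    records: dict
    te_families: tuple[str, ...]
    polyploids: tuple[str, ...]
    category_order: tuple[str, ...]

    def te_record(self, te: str) -> dict:
        return self.records[te]

    def category_counts(self, te: str) -> dict[str, int]:
        if self.table_id not in ("table5_new", "table5_lost"):
            raise ValidationError(f"{self.table_id} has no sharing categories")
        rec = self.records[te]
        return {c: rec["categories"][c][0] for c in self.category_order}

    def validate(self) -> None:
        if self.table_id == "table3":
            for te in self.te_families:
                r = self.records[te]
                if r["shared"][0] + r["maternal_specific"][0] + r["paternal_specific"][0] != r["total"]:
                    raise ValidationError(f"table3 {te}: parts do not sum to total")
        elif self.table_id in ("table5_new", "table5_lost"):
            members = {
                "NUD": [c for c in self.category_order if "NUD" in c.split("+")],
                "REP": [c for c in self.category_order if "REP" in c.split("+")],
                "ISL": [c for c in self.category_order if "ISL" in c.split("+")],
            }
            for te in self.te_families:
                cats = self.category_counts(te)
                r = self.records[te]
                if sum(cats.values()) != r["in_all"][0]:
                    raise ValidationError(
                        f"{self.table_id} {te}: categories do not sum to in_all")
                for taxon, cs in members.items():
                    if sum(cats[c] for c in cs) != r["per_taxon"][taxon][0]:
                        raise ValidationError(
                            f"{self.table_id} {te}: {taxon} count != category sum")


def _load_raw() -> dict:
    with resources.files("ssapkit.data").joinpath("printed_tables.json").open() as fh:
        return json.load(fh)


def load_paper_fixture(table_id: str) -> CountFixture:
    """Load the packaged transcription of one printed count table."""
    if table_id not in FIXTURE_IDS:
        raise KeyError(f"unknown table_id {table_id!r}; expected one of {FIXTURE_IDS}")
    raw = _load_raw()
    records = {k: v for k, v in raw[table_id].items() if not k.startswith("_")}
    if table_id == "table3":
        records["_totals"] = raw["table3"]["_totals"]
    if table_id in ("table5_new", "table5_lost"):
        records["_all_tes"] = raw[table_id]["_all_tes"]
    fx = CountFixture(
        table_id=table_id,
        records=records,
        te_families=tuple(raw["te_families"]),
        polyploids=tuple(raw["polyploids"]),
        category_order=tuple(raw["category_order"]),
    )
    fx.validate()
    return fx


def load_printed_metadata() -> dict:
    """Prose totals, Table 6 ANOVA entries and sampling sizes as printed."""
    raw = _load_raw()
    return {
        "prose": raw["prose"],
        "table6": raw["table6"],
        "accessions_per_taxon": raw["accessions_per_taxon"],
        "te_families": raw["te_families"],
        "polyploids": raw["polyploids"],
    }
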