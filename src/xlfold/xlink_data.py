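"""Cross-link identification data model, target-decoy FDR, and filtering.

Photo-cross-linkers such as sulfo-SDA carry an NHS-ester end that reacts with
lysine, serine, threonine, tyrosine or the protein N terminus, and a
photo-activatable diazirine end that inserts into any nearby residue.  A
database search of the fragmentation spectra yields peptide-spectrum matches
(PSMs) for cross-linked peptide pairs; each PSM localises two linked residues
and carries a search score plus a target/decoy class.  This module turns such
PSM tables into a deduplicated, error-controlled set of residue-pair
constraints ready for structure modeling.

Error control follows the target-decoy strategy for cross-links, where a
match can pair two target peptides (TT), one target and one decoy (TD), or
two decoys (DD).  A DD match estimates the rate at which *both* peptides of a
false match are decoys, so the number of false TT matches above a score
threshold is estimated as TD - DD and

    FDR(s) = max(0, TD(s) - DD(s)) / TT(s)

over all matches with score >= s.  q-values are the running minimum of FDR
from the most permissive threshold upward, so they are non-increasing with
score.  Inputs that only carry a single target/decoy flag fall back to the
classic FDR = D / T estimate (``mode="td"``).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "EndChemistry",
    "DecoyClass",
    "ResidueSite",
    "CrossLinkMatch",
    "CrossLink",
    "CrossLinkSet",
    "TableDialect",
    "read_crosslink_table",
    "write_crosslink_table",
    "estimate_fdr",
    "unique_residue_pairs",
    "filter_links",
    "constraints_per_residue",
]

NHS_RESIDUES = frozenset("KSTY")


class EndChemistry(Enum):
    NHS = "NHS"
    DIAZIRINE = "DIAZIRINE"


class DecoyClass(Enum):
    TT = "TT"
    TD = "TD"
    DD = "DD"


@dataclass(frozen=True)
class ResidueSite:
    """One linked residue: protein, 1-based index, residue type and end chemistry."""

    protein_id: str
    residue_index: int
    amino_acid: str = "X"
    end_chemistry: EndChemistry = EndChemistry.DIAZIRINE

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")

    def validate_chemistry(self, sequence: str) -> bool:
        """Check NHS-end specificity (K/S/T/Y or N terminus) against a sequence."""
        if self.end_chemistry is not EndChemistry.NHS:
            return True
        if self.residue_index == 1:
            return True
        if self.residue_index > len(sequence):
            return False
        return sequence[self.residue_index - 1] in NHS_RESIDUES


@dataclass
class CrossLinkMatch:
    """A peptide-spectrum match for one cross-linked residue pair."""

    spectrum_id: str
    site_a: ResidueSite  # NHS-ester end
    site_b: ResidueSite  # diazirine end
    score: float
    decoy_class: DecoyClass
    q_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError(f"match score must be finite, got {self.score}")
        if self.q_value is not None and not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value must lie in [0, 1], got {self.q_value}")


@dataclass(frozen=True)
class CrossLink:
    """A unique residue pair, aggregated over its PSMs (best score kept)."""

    site_a: ResidueSite
    site_b: ResidueSite
    best_score: float
    q_value: float

    @property
    def sequence_separation(self) -> int:
        return abs(self.site_a.residue_index - self.site_b.residue_index)

    @property
    def pair(self) -> tuple[int, int]:
        i, j = self.site_a.residue_index, self.site_b.residue_index
        return (i, j) if i <= j else (j, i)


@dataclass
class CrossLinkSet:
    """An ordered, duplicate-free collection of unique cross-links."""

    links: list[CrossLink] = field(default_factory=list)
    protein_length: Optional[int] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [self._key(ln) for ln in self.links]
        if len(set(keys)) != len(keys):
            raise ValueError("CrossLinkSet contains duplicate residue pairs")
        if self.protein_length is not None:
            top = max(
                (max(ln.site_a.residue_index, ln.site_b.residue_index) for ln in self.links),
                default=0,
            )
            if self.protein_length < top:
                raise ValueError(
                    f"protein_length {self.protein_length} < max residue index {top}"
                )

    @staticmethod
    def _key(link: CrossLink) -> tuple:
        pa, pb = link.site_a.protein_id, link.site_b.protein_id
        ia, ib = link.site_a.residue_index, link.site_b.residue_index
        return tuple(sorted([(pa, ia), (pb, ib)]))

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(self.links)


@dataclass
class TableDialect:
    """Column-name mapping for cross-link tables (CSV or TSV).

    ``delimiter=None`` auto-detects from the header line.  ``decoy_mode``
    selects between three-class TT/TD/DD accounting and a plain
    target/decoy flag (values ``T``/``D`` or ``TT``..).
    """

    protein_a: str = "Protein1"
    protein_b: str = "Protein2"
    site_a: str = "FromSite"
    site_b: str = "ToSite"
    score: str = "Score"
    decoy_class: str = "DecoyClass"
    spectrum_id: Optional[str] = None
    delimiter: Optional[str] = None
    decoy_mode: str = "ttdd"  # "ttdd" or "td"


class SchemaError(ValueError):
    pass


class RowParseError(ValueError):
    pass


_DECOY_ALIASES = {
    "TT": DecoyClass.TT,
    "TD": DecoyClass.TD,
    "DT": DecoyClass.TD,
    "DD": DecoyClass.DD,
    "T": DecoyClass.TT,
    "TARGET": DecoyClass.TT,
    "D": DecoyClass.TD,
    "DECOY": DecoyClass.TD,
}


def read_crosslink_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[CrossLinkMatch]:
    """Read a cross-link PSM table into :class:`CrossLinkMatch` records.

    Row order is preserved.  Raises :class:`SchemaError` when a required
    column is missing and :class:`RowParseError` (with the 1-based data-row
    number) when a site index does not parse as an integer.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            return []
        delim = dialect.delimiter
        if delim is None:
            delim = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        required = [dialect.protein_a, dialect.protein_b, dialect.site_a,
                    dialect.site_b, dialect.score, dialect.decoy_class]
        for col in required:
            if col not in header:
                raise SchemaError(f"required column {col!r} not found in {path.name} "
                                  f"(header: {header})")
        matches: list[CrossLinkMatch] = []
        for rownum, row in enumerate(reader, start=1):
            try:
                ia = int(row[dialect.site_a])
                ib = int(row[dialect.site_b])
            except (TypeError, ValueError) as exc:
                raise RowParseError(f"row {rownum}: non-integer residue site "
                                    f"({row[dialect.site_a]!r}, {row[dialect.site_b]!r})") from exc
            cls_raw = (row[dialect.decoy_class] or "").strip().upper()
            if cls_raw not in _DECOY_ALIASES:
                raise RowParseError(f"row {rownum}: unknown decoy class {cls_raw!r}")
            spectrum = row.get(dialect.spectrum_id, "") if dialect.spectrum_id else f"psm{rownum}"
            aa_a = (row.get("ResidueA") or "X").strip() or "X"
            aa_b = (row.get("ResidueB") or "X").strip() or "X"
            matches.append(
                CrossLinkMatch(
                    spectrum_id=spectrum,
                    site_a=ResidueSite(row[dialect.protein_a], ia, aa_a, EndChemistry.NHS),
                    site_b=ResidueSite(row[dialect.protein_b], ib, aa_b, EndChemistry.DIAZIRINE),
                    score=float(row[dialect.score]),
                    decoy_class=_DECOY_ALIASES[cls_raw],
                )
            )
    return matches


def write_crosslink_table(
    matches: Iterable[CrossLinkMatch], path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Write PSMs in the same dialect :func:`read_crosslink_table` consumes."""
    dialect = dialect or TableDialect()
    delim = dialect.delimiter or ","
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow([dialect.protein_a, dialect.protein_b, dialect.site_a,
                         dialect.site_b, "ResidueA", "ResidueB",
                         dialect.score, dialect.decoy_class])
        for m in matches:
            writer.writerow([m.site_a.protein_id, m.site_b.protein_id,
                             m.site_a.residue_index, m.site_b.residue_index,
                             m.site_a.amino_acid, m.site_b.amino_acid,
                             m.score, m.decoy_class.value])


def estimate_fdr(
    matches: Sequence[CrossLinkMatch], mode: str = "ttdd"
) -> list[CrossLinkMatch]:
    """Assign q-values by target-decoy FDR estimation.

    For every threshold s taken at a match score, counts TT/TD/DD among
    matches with score >= s and sets FDR(s) = max(0, TD - DD) / TT
    (``mode="ttdd"``) or FDR(s) = D / T (``mode="td"``, TD and DD both count
    as decoys).  q-values are the running minimum of FDR from the lowest
    threshold upward.  When no TT match is at or above a threshold the FDR
    there is undefined and reported as 1.0.

    Returns a new list (same order as the input) with ``q_value`` set.
    """
    if mode not in ("ttdd", "td"):
        raise ValueError(f"unknown FDR mode {mode!r}")
    if not matches:
        return []
    order = sorted(range(len(matches)), key=lambda k: -matches[k].score)
    # one threshold per distinct score; ties share counts and FDR
    tt = td = dd = 0
    fdr_of_score: dict[float, float] = {}
    pos = 0
    while pos < len(order):
        s = matches[order[pos]].score
        while pos < len(order) and matches[order[pos]].score == s:
            cls = matches[order[pos]].decoy_class
            if cls is DecoyClass.TT:
                tt += 1
            elif cls is DecoyClass.TD:
                td += 1
            else:
                dd += 1
            pos += 1
        if tt == 0:
            fdr_of_score[s] = 1.0
        elif mode == "ttdd":
            fdr_of_score[s] = max(0, td - dd) / tt
        else:
            fdr_of_score[s] = min(1.0, (td + dd) / tt)
    # running minimum from the most permissive (lowest-score) threshold upward
    q_of_score: dict[float, float] = {}
    running = math.inf
    for s in sorted(fdr_of_score):
        running = min(running, fdr_of_score[s])
        q_of_score[s] = min(running, 1.0)
    out = [replace(m) for m in matches]
    for m in out:
        m.q_value = q_of_score[m.score]
    return out


def unique_residue_pairs(matches: Iterable[CrossLinkMatch]) -> CrossLinkSet:
    """Collapse TT PSMs to unique unordered residue pairs, keeping the best score.

    Pairs are canonicalised with the smaller residue index first (end
    chemistry labels travel with their sites).  Requires q-values to be set.
    """
    best: dict[tuple, CrossLinkMatch] = {}
    for m in matches:
        if m.decoy_class is not DecoyClass.TT:
            continue
        if m.q_value is None:
            raise ValueError("q_values must be set before deduplication; run estimate_fdr")
        key = tuple(sorted([(m.site_a.protein_id, m.site_a.residue_index),
                            (m.site_b.protein_id, m.site_b.residue_index)]))
        prev = best.get(key)
        if prev is None or m.score > prev.score:
            best[key] = m
    links = []
    for m in best.values():
        a, b = m.site_a, m.site_b
        if (b.protein_id, b.residue_index) < (a.protein_id, a.residue_index):
            a, b = b, a
        links.append(CrossLink(site_a=a, site_b=b, best_score=m.score, q_value=m.q_value))
    links.sort(key=lambda ln: (ln.site_a.protein_id, ln.pair))
    return CrossLinkSet(links=links, provenance="unique_residue_pairs")


def filter_links(linkset: CrossLinkSet, max_fdr: float, min_separation: int) -> CrossLinkSet:
    """Keep links with q_value <= max_fdr and sequence separation strictly > min_separation.

    The strict inequality matters: with ``min_separation=12`` a pair exactly
    12 residues apart is dropped.
    """
    if min_separation < 0:
        raise ValueError(f"min_separation must be >= 0, got {min_separation}")
    kept = [ln for ln in linkset.links
            if ln.q_value <= max_fdr and ln.sequence_separation > min_separation]
    return CrossLinkSet(links=kept, protein_length=linkset.protein_length,
                        provenance=f"{linkset.provenance}|filter(q<={max_fdr},sep>{min_separation})")


def constraints_per_residue(linkset: CrossLinkSet, protein_length: int) -> float:
    """Constraint density: number of unique links divided by protein length."""
    if protein_length < 1:
        raise ValueError(f"protein_length must be >= 1, got {protein_length}")
    return len(linkset) / protein_length
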