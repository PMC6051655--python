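"""Repeat annotation parsing and the subfamily/family/class taxonomy.

Repeat loci come from RepeatMasker output, either the native ``.out``
dialect (whitespace-delimited, three header lines, 1-based inclusive
coordinates, slash-joined ``class/family`` labels) or the UCSC genome
browser ``rmsk`` table (tab-separated, 0-based half-open, separate
``repClass``/``repFamily`` columns).  Internally everything is 0-based
half-open; conversion happens only at the parse/write boundary.

The three-level taxonomy (subfamily -> family -> class, e.g.
AluYa5 -> Alu -> SINE) defines both the count-aggregation units and the
background for class/family enrichment tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RepeatLocus",
    "RepeatTaxonomy",
    "parse_rmsk",
    "build_taxonomy",
    "write_bed",
    "write_taxonomy_tsv",
    "collapse_to_others",
]

#: Classes kept as-is when collapsing minor classes into "Others".
MAJOR_CLASSES = ("DNA", "SINE", "LINE", "LTR", "Satellite")


@dataclass(frozen=True)
class RepeatLocus:
    """One genomic repeat interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str
    class_: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                f"for {self.subfamily}: require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatTaxonomy:
    """Subfamily -> (family, class) mapping with per-level counts."""

    parent: dict[str, tuple[str, str]]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = sorted({c for _, c in self.parent.values()})

    @property
    def n_subfamilies(self) -> int:
        return len(self.parent)

    @property
    def n_families(self) -> int:
        return len({f for f, _ in self.parent.values()})

    @property
    def n_classes(self) -> int:
        return len({c for _, c in self.parent.values()})

    def family_of(self, subfamily: str) -> str:
        return self.parent[subfamily][0]

    def class_of(self, subfamily: str) -> str:
        return self.parent[subfamily][1]

    def subfamilies(self) -> list[str]:
        return sorted(self.parent)

    def members(self, level: str, name: str) -> set[str]:
        """Subfamilies whose family (level='family') or class (level='class_')
        equals *name*."""
        idx = {"family": 0, "class_": 1}[level]
        return {sf for sf, p in self.parent.items() if p[idx] == name}


def _split_class_family(label: str) -> tuple[str, str]:
    # RepeatMasker writes "LTR/ERVK"; single-level labels like
    # "Simple_repeat" carry no family, so family = class.
    if "/" in label:
        class_, family = label.split("/", 1)
    else:
        class_ = family = label
    return class_, family


def parse_rmsk(path: str | Path, dialect: str = "ucsc_table") -> list[RepeatLocus]:
    """Parse a repeat annotation file into normalized loci.

    Parameters
    ----------
    path
        Annotation file.
    dialect
        ``"ucsc_table"`` — UCSC rmsk tab-separated table, with or without a
        header line; 0-based half-open coordinates.
        ``"rm_out"`` — RepeatMasker ``.out``: three header lines then
        whitespace-delimited rows with 1-based inclusive coordinates.

    Returns
    -------
    Loci sorted by (chrom, start), in 0-based half-open coordinates.
    """
    path = Path(path)
    if dialect == "ucsc_table":
        loci = _parse_ucsc(path)
    elif dialect == "rm_out":
        loci = _parse_rm_out(path)
    else:
        raise ValueError(f"unknown rmsk dialect {dialect!r}")
    loci.sort(key=lambda l: (l.chrom, l.start, l.end))
    return loci


# UCSC rmsk column names -> positions in the full 17-column table.
_UCSC_COLS = {
    "genoName": 5, "genoStart": 6, "genoEnd": 7, "strand": 9,
    "repName": 10, "repClass": 11, "repFamily": 12,
}


def _parse_ucsc(path: Path) -> list[RepeatLocus]:
    loci: list[RepeatLocus] = []
    with open(path) as fh:
        first = fh.readline()
        if not first:
            return loci
        header_fields = first.rstrip("\n").split("\t")
        if "genoName" in header_fields:
            idx = {name: header_fields.index(name) for name in _UCSC_COLS}
            lines = enumerate(fh, start=2)
        else:
            # headerless: accept either the full 17-column dump or the
            # 7-column projection (genoName..repFamily) this package writes
            nf = len(header_fields)
            if nf >= 17:
                idx = dict(_UCSC_COLS)
            elif nf == 7:
                idx = {n: i for i, n in enumerate(
                    ["genoName", "genoStart", "genoEnd", "strand",
                     "repName", "repClass", "repFamily"])}
            else:
                raise ValueError(
                    f"{path}:1: expected 7 or >=17 tab-separated columns, got {nf}"
                )
            lines = enumerate([first] + fh.readlines(), start=1)
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                loci.append(RepeatLocus(
                    chrom=fields[idx["genoName"]],
                    start=int(fields[idx["genoStart"]]),
                    end=int(fields[idx["genoEnd"]]),
                    strand=fields[idx["strand"]],
                    subfamily=fields[idx["repName"]],
                    class_=fields[idx["repClass"]],
                    family=fields[idx["repFamily"]],
                ))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed UCSC rmsk row: {exc}") from exc
    return loci


def _parse_rm_out(path: Path) -> list[RepeatLocus]:
    loci: list[RepeatLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3:  # SW-score banner + column names + blank line
                continue
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ValueError(
                    f"{path}:{lineno}: malformed .out row, "
                    f"expected >=11 whitespace fields, got {len(fields)}"
                )
            try:
                chrom = fields[4]
                begin = int(fields[5])  # 1-based inclusive
                end = int(fields[6])
                strand = "-" if fields[8] == "C" else "+"
                subfamily = fields[9]
                class_, family = _split_class_family(fields[10])
                loci.append(RepeatLocus(
                    chrom=chrom, start=begin - 1, end=end, strand=strand,
                    subfamily=subfamily, family=family, class_=class_,
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed .out row: {exc}") from exc
    return loci


def build_taxonomy(loci: Sequence[RepeatLocus]) -> RepeatTaxonomy:
    """Build the subfamily->family->class taxonomy from parsed loci.

    Raises if the locus list is empty or a subfamily claims two distinct
    (family, class) parents.
    """
    if not loci:
        raise ValueError("cannot build a taxonomy from an empty locus list")
    parent: dict[str, tuple[str, str]] = {}
    conflicts: list[str] = []
    for locus in loci:
        pair = (locus.family, locus.class_)
        seen = parent.get(locus.subfamily)
        if seen is None:
            parent[locus.subfamily] = pair
        elif seen != pair:
            conflicts.append(
                f"{locus.subfamily}: {seen[1]}/{seen[0]} vs {pair[1]}/{pair[0]}"
            )
    if conflicts:
        raise ValueError(
            "conflicting subfamily parentage: " + "; ".join(sorted(set(conflicts)))
        )
    return RepeatTaxonomy(parent=parent)


def collapse_to_others(
    taxonomy: RepeatTaxonomy, keep: Iterable[str] = MAJOR_CLASSES
) -> RepeatTaxonomy:
    """Relabel classes outside *keep* as "Others" (reporting-level view;
    SVA, simple repeats, snRNA, tRNA etc. end up in one bucket)."""
    keep = set(keep)
    parent = {
        sf: (fam, cls if cls in keep else "Others")
        for sf, (fam, cls) in taxonomy.parent.items()
    }
    return RepeatTaxonomy(parent=parent)


def write_bed(loci: Sequence[RepeatLocus], path: str | Path) -> None:
    """Write loci as BED6+3 (name=subfamily; extra cols family, class)."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.subfamily}\t0\t{l.strand}"
                f"\t{l.family}\t{l.class_}\t{l.length}\n"
            )


def write_taxonomy_tsv(taxonomy: RepeatTaxonomy, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("subfamily\tfamily\tclass\n")
        for sf in taxonomy.subfamilies():
            fam, cls = taxonomy.parent[sf]
            fh.write(f"{sf}\t{fam}\t{cls}\n")


def read_taxonomy_tsv(path: str | Path) -> RepeatTaxonomy:
    parent: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("subfamily\t"):
            raise ValueError(f"{path}:1: expected 'subfamily\\tfamily\\tclass' header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                sf, fam, cls = line.rstrip("\n").split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed taxonomy row") from exc
            parent[sf] = (fam, cls)
    return RepeatTaxonomy(parent=parent)


def level_counts(loci: Sequence[RepeatLocus]) -> dict[str, int]:
    """Distinct-name counts at each taxonomy level (plus locus count)."""
    return {
        "classes": len({l.class_ for l in loci}),
        "families": len({l.family for l in loci}),
        "subfamilies": len({l.subfamily for l in loci}),
        "loci": len(loci),
    }
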