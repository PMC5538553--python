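"""Readers/writers for the standard formats the toolkit touches.

Conventions are fixed here once: BED is 0-based half-open, alignment columns
are 1-based in reports, T is normalized to U and sequences are upper-cased on
read, and structure strings are normalized to the plain ``()/.`` alphabet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import AlignIO

GAP_CHARS = frozenset("-._~")
_OPEN = frozenset("(<[{")
_CLOSE = frozenset(")>]}")


class StructureError(ValueError):
    """Raised for unbalanced or crossing consensus structures."""


class ParseError(ValueError):
    """Raised for malformed input files."""


def normalize_sequence(seq: str) -> str:
    """Upper-case, map T->U and any gap-like character to '-'."""
    out = []
    for c in seq.upper():
        if c in GAP_CHARS:
            out.append("-")
        elif c == "T":
            out.append("U")
        else:
            out.append(c)
    return "".join(out)


def normalize_structure(ss: str) -> str:
    """Map WUSS bracket symbols to ``(``/``)`` and everything else to ``.``.

    Pseudoknot letters (Aa, Bb, ...) are treated as unpaired: the toolkit
    scores pseudoknot-free consensus structures only.
    """
    out = []
    for c in ss:
        if c in _OPEN:
            out.append("(")
        elif c in _CLOSE:
            out.append(")")
        else:
            out.append(".")
    return "".join(out)


def structure_pairs(structure: str, h: int = 3) -> list[tuple[int, int]]:
    """Return base pairs (1-based column indices) of a dot-bracket string.

    Raises :class:`StructureError` on unbalanced brackets (reporting the
    1-based offending column) or on pairs enclosing fewer than ``h`` columns.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for col, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(col)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced at column {col}")
            pairs.append((stack.pop(), col))
    if stack:
        # unmatched opens are only detectable once the scan ends
        raise StructureError(f"unbalanced at column {len(structure)}")
    for i, j in pairs:
        if j - i <= h:
            raise StructureError(f"pair ({i},{j}) closer than minimum hairpin size {h}")
    return sorted(pairs)


@dataclass
class AnnotatedAlignment:
    """A gapped multiple alignment with a consensus secondary structure.

    ``rows`` is an ordered list of ``(name, sequence)``; all sequences and the
    structure string share the same length. The structure is dot-bracket,
    balanced and non-crossing.
    """

    rows: list[tuple[str, str]]
    structure: str
    id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, h: int = 3) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        L = len(self.structure)
        if L < 1:
            raise ValueError("empty structure line")
        names = [n for n, _ in self.rows]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate row names: {dup}")
        for name, seq in self.rows:
            if len(seq) != L:
                raise ParseError(
                    f"row {name!r} has length {len(seq)}, expected {L}"
                )
        structure_pairs(self.structure, h=h)  # raises on malformed structure

    @property
    def length(self) -> int:
        return len(self.structure)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.rows]

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.rows]

    def pairs(self, h: int = 3) -> list[tuple[int, int]]:
        return structure_pairs(self.structure, h=h)

    def ungapped(self, name: str) -> str:
        seq = dict(self.rows)[name]
        return "".join(c for c in seq if c != "-")

    def column_to_position(self, name: str) -> dict[int, int]:
        """Map 1-based alignment columns to 1-based ungapped positions."""
        seq = dict(self.rows)[name]
        mapping = {}
        pos = 0
        for col, c in enumerate(seq, start=1):
            if c != "-":
                pos += 1
                mapping[col] = pos
        return mapping


def read_stockholm(path) -> AnnotatedAlignment:
    """Read a single Stockholm alignment with a ``#=GC SS_cons`` line."""
    try:
        aln = AlignIO.read(path, "stockholm")
    except ValueError as exc:
        raise ParseError(f"cannot parse Stockholm file {path}: {exc}") from exc
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise ParseError(f"{path}: no #=GC SS_cons consensus-structure line")
    rows = [(rec.id, normalize_sequence(str(rec.seq))) for rec in aln]
    name = getattr(path, "name", str(path))
    return AnnotatedAlignment(rows=rows, structure=normalize_structure(ss), id=name)


def write_stockholm(aln: AnnotatedAlignment, path) -> None:
    name_w = max(len(n) for n in aln.names)
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for name, seq in aln.rows:
            fh.write(f"{name:<{name_w}} {seq}\n")
        fh.write(f"{'#=GC SS_cons':<{name_w}} {aln.structure}\n")
        fh.write("//\n")


def read_fasta_with_structure(path, structure: str, id: str = "") -> AnnotatedAlignment:
    """Read a gapped FASTA alignment plus an explicit dot-bracket string."""
    from Bio import SeqIO

    rows = [(rec.id, normalize_sequence(str(rec.seq))) for rec in SeqIO.parse(path, "fasta")]
    return AnnotatedAlignment(rows=rows, structure=normalize_structure(structure), id=id or str(path))


# ---------------------------------------------------------------------------
# Trees


def read_newick(path_or_string):
    """Read a rooted Newick tree with branch lengths into a PhyloTree."""
    from crstool.phylo_models import PhyloTree

    return PhyloTree.from_newick(path_or_string)


# ---------------------------------------------------------------------------
# Genomic intervals


class Interval(NamedTuple):
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0
    strand: str = "."

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:  # type: ignore[override]
        return self.end - self.start


@dataclass
class IntervalSet:
    """A list of 0-based half-open genomic intervals (BED semantics)."""

    records: list[Interval] = field(default_factory=list)
    ncols: int = 6

    def __post_init__(self) -> None:
        for rec in self.records:
            if not 0 <= rec.start < rec.end:
                raise ValueError(f"invalid interval {rec.chrom}:{rec.start}-{rec.end}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(sorted(self.records, key=lambda r: (r.chrom, r.start, r.end)), self.ncols)

    def total_bases(self) -> int:
        return sum(len(r) for r in self.records)


def read_bed(path) -> IntervalSet:
    """Read BED3-BED6; strand defaults to '.' when the column is absent."""
    records = []
    ncols = 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path} line {lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else "."
            score = _num(fields[4]) if len(fields) > 4 else 0
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in "+-.":
                raise ParseError(f"{path} line {lineno}: bad strand {strand!r}")
            ncols = max(ncols, min(len(fields), 6))
            records.append(Interval(chrom, start, end, name, score, strand))
    return IntervalSet(records, ncols=ncols)


def _num(s: str) -> float:
    x = float(s)
    return int(x) if x == int(x) else x


def write_bed(ivs: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for r in ivs.records:
            fields = [r.chrom, str(r.start), str(r.end), r.name, str(r.score), r.strand]
            fh.write("\t".join(fields[: ivs.ncols]) + "\n")


def merge_intervals(ivs: IntervalSet) -> IntervalSet:
    """Union of strictly overlapping intervals, strand-ignored.

    Abutting half-open intervals ([0,10) and [10,20)) do not merge: region
    definition is literal overlap. Output is sorted and disjoint.
    """
    out: list[Interval] = []
    for rec in ivs.sorted():
        if out and out[-1].chrom == rec.chrom and rec.start < out[-1].end:
            last = out[-1]
            out[-1] = Interval(last.chrom, last.start, max(last.end, rec.end), last.name, last.score, ".")
        else:
            out.append(Interval(rec.chrom, rec.start, rec.end, rec.name, rec.score, "."))
    return IntervalSet(out, ncols=ivs.ncols)


@dataclass
class GenomeWindows:
    """Fixed-width windows annotated with GC content and sequence identity."""

    intervals: IntervalSet
    gc: Sequence[float]
    si: Sequence[float]
    width: int = 100

    def __post_init__(self) -> None:
        n = len(self.intervals)
        if not (len(self.gc) == len(self.si) == n):
            raise ValueError("gc/si annotation length mismatch")
        for rec in self.intervals:
            if len(rec) != self.width:
                raise ValueError(f"window {rec} is not {self.width} bp wide")
        for v in list(self.gc) + list(self.si):
            if not 0.0 <= v <= 1.0:
                raise ValueError("gc/si must lie in [0,1]")


# ---------------------------------------------------------------------------
# Alignment summary statistics


def alignment_stats(aln: AnnotatedAlignment) -> tuple[float, float, int, int]:
    """Return (gc, si, length, n_species).

    gc is G+C over all non-gap characters of all rows. si is the mean over
    row pairs of identical-column counts divided by the gap-included alignment
    length L; a column gapped in either sequence of a pair is a mismatch.
    A single-row alignment reports si = 1.0 (with a warning).
    """
    L = aln.length
    seqs = aln.sequences
    ngap_chars = 0
    gc_chars = 0
    for seq in seqs:
        for c in seq:
            if c != "-":
                ngap_chars += 1
                if c in "GC":
                    gc_chars += 1
    gc = gc_chars / ngap_chars if ngap_chars else 0.0
    n = len(seqs)
    if n == 1:
        warnings.warn("single-row alignment: si reported as 1.0 by convention")
        return gc, 1.0, L, n
    ident_sum = 0.0
    npairs = 0
    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = seqs[a], seqs[b]
            ident = sum(
                1 for x, y in zip(sa, sb) if x == y and x != "-"
            )
            ident_sum += ident / L
            npairs += 1
    return gc, ident_sum / npairs, L, n


def filter_alignment_blocks(
    blocks: Iterable[AnnotatedAlignment],
    species_class: Mapping[str, str],
    anchor: str,
    min_len: int = 60,
    min_nonprimates: int = 3,
) -> list[AnnotatedAlignment]:
    """Keep blocks of length >= min_len containing the anchor species and at
    least ``min_nonprimates`` rows classed as nonprimate."""
    kept = []
    for blk in blocks:
        for name in blk.names:
            if name not in species_class:
                raise KeyError(f"species {name!r} missing from species_class")
        if blk.length < min_len:
            continue
        if anchor not in blk.names:
            continue
        n_nonprim = sum(
            1 for name in blk.names if species_class[name] == "nonprimate"
        )
        if n_nonprim < min_nonprimates:
            continue
        kept.append(blk)
    return kept
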