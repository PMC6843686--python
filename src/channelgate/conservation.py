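"""Alignment-column conservation and subunit-specific residue profiles.

Operates on user-supplied multiple sequence alignments (FASTA); no
database searching.  Column indices are 1-based alignment coordinates,
matching the convention of printed column numbers in curated alignment
files.  Conservation of a column is the majority-residue count divided
by the non-gap count (gaps excluded from the denominator by default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from io import StringIO

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .errors import FormatError, InputError

GAP_CHARS = frozenset("-.")


def read_alignment(source) -> MultipleSeqAlignment:
    """Read a FASTA multiple sequence alignment from a path or string."""
    if isinstance(source, MultipleSeqAlignment):
        return source
    text = str(source)
    if "\n" in text or text.lstrip().startswith(">"):
        handle = StringIO(text)
    else:
        handle = open(text)
    try:
        alignment = AlignIO.read(handle, "fasta")
    except ValueError as exc:
        raise FormatError(f"not a valid FASTA alignment: {exc}") from exc
    finally:
        handle.close()
    return alignment


@dataclass
class AlignmentColumnProfile:
    """Exact residue counts of one alignment column (1-based index)."""

    column: int
    frequencies: dict          # residue -> count (gaps excluded)
    gap_fraction: float
    majority_residue: str
    conservation: float        # majority count / non-gap count

    @property
    def non_gap_count(self) -> int:
        return sum(self.frequencies.values())


def column_profile(alignment, column: int) -> AlignmentColumnProfile:
    """Residue frequency profile of one alignment column.

    ``column`` is 1-based; counting is exact and invariant under
    sequence reordering.
    """
    aln = read_alignment(alignment)
    width = aln.get_alignment_length()
    lengths = {len(rec.seq) for rec in aln}
    if len(lengths) > 1:
        raise FormatError(f"unequal sequence lengths: {sorted(lengths)}")
    if not 1 <= column <= width:
        raise InputError(f"column {column} outside alignment width {width}")

    residues = [str(rec.seq[column - 1]).upper() for rec in aln]
    gaps = sum(r in GAP_CHARS for r in residues)
    counts = Counter(r for r in residues if r not in GAP_CHARS)
    if counts:
        majority, majority_count = max(
            counts.items(), key=lambda item: (item[1], -ord(item[0][0])))
        conservation = majority_count / sum(counts.values())
    else:
        majority, conservation = "-", 0.0
    return AlignmentColumnProfile(
        column=column,
        frequencies=dict(sorted(counts.items())),
        gap_fraction=gaps / len(residues),
        majority_residue=majority,
        conservation=conservation,
    )


def motif_conservation(alignment, start_column: int, motif: str,
                       allow_gaps: bool = False) -> tuple[int, int]:
    """Count sequences whose window matches a residue motif exactly.

    The window spans ``start_column`` (1-based) through
    ``start_column + len(motif) - 1``.  With ``allow_gaps`` the window
    instead collects the first ``len(motif)`` non-gap residues from the
    start column onward, so a motif interrupted by alignment gap columns
    still counts.  Returns ``(matching, total)``.
    """
    aln = read_alignment(alignment)
    motif = motif.upper()
    width = aln.get_alignment_length()
    end_column = start_column + len(motif) - 1
    if not (1 <= start_column and end_column <= width):
        raise InputError(
            f"motif window {start_column}-{end_column} outside width {width}")

    matching = 0
    for rec in aln:
        if allow_gaps:
            window = "".join(
                c for c in str(rec.seq[start_column - 1:]).upper()
                if c not in GAP_CHARS)[:len(motif)]
        else:
            window = str(rec.seq[start_column - 1:end_column]).upper()
        if window == motif:
            matching += 1
    return matching, len(aln)


@dataclass
class SubunitColumnReport:
    """Per-group residue distributions at selected columns."""

    columns: list
    group_frequencies: dict    # group -> column -> residue -> count
    discriminating: list       # columns where group majorities are disjoint


def subunit_cluster_report(alignment, groups: dict, columns) -> SubunitColumnReport:
    """Group-resolved residue distributions at selected columns.

    ``groups`` maps every sequence ID to a group label (e.g. GluN1,
    GluN2, GluN3, AMPA, Kainate).  A column is flagged as
    group-discriminating when the majority residues of the groups are
    pairwise distinct.
    """
    aln = read_alignment(alignment)
    unmapped = [rec.id for rec in aln if rec.id not in groups]
    if unmapped:
        raise InputError(f"sequences without a group: {unmapped[:5]}")

    width = aln.get_alignment_length()
    labels = sorted(set(groups.values()))
    freqs = {g: {} for g in labels}
    discriminating = []
    for column in columns:
        if not 1 <= column <= width:
            raise InputError(f"column {column} outside alignment width {width}")
        majorities = {}
        for g in labels:
            residues = [
                str(rec.seq[column - 1]).upper()
                for rec in aln if groups[rec.id] == g
            ]
            counts = Counter(r for r in residues if r not in GAP_CHARS)
            freqs[g][column] = dict(sorted(counts.items()))
            if counts:
                majorities[g] = max(
                    counts.items(), key=lambda item: (item[1], -ord(item[0][0])))[0]
        values = list(majorities.values())
        if len(labels) > 1 and len(set(values)) == len(values):
            discriminating.append(column)
    return SubunitColumnReport(list(columns), freqs, discriminating)
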