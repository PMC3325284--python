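"""Readers, writers and in-memory containers for the external formats the
pipeline touches: aligned FASTA per genus, GFF3 feature annotations of the
reference sequence, inversion declarations, and the derived BED/TSV outputs.

Coordinate conventions
----------------------
All public coordinates are 1-based inclusive (GFF3 style).  BED output is
written 0-based half-open per the BED standard.  Alignment coordinates index
columns of the gapped alignment; reference coordinates index residues of the
ungapped reference sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

GAP = "-"
RESIDUES = frozenset("ACGT")
#: IUPAC ambiguity codes (including N) are retained at load and treated as
#: missing data downstream, so they never create artificial polymorphism.
AMBIGUOUS = frozenset("RYSWKMBDHVN")
_VALID_CHARS = RESIDUES | AMBIGUOUS | {GAP}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


class AlignmentError(ValueError):
    """Malformed or inconsistent alignment input."""


class FormatError(ValueError):
    """Malformed annotation or declaration file."""


class CoordinateError(ValueError):
    """A coordinate falls outside the addressed sequence."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# GenusAlignment


@dataclass(frozen=True)
class GenusAlignment:
    """One genus's aligned congeneric sequences plus the index of the
    annotated reference row.

    ``inversion_spans`` records inversions that have been separated
    (re-oriented) in this alignment, as ``(sample_id, aln_start, aln_end)``
    tuples; the sliding-window scan uses them for the per-window inversion
    indicator.
    """

    genus_label: str
    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    reference_index: int = 0
    inversion_spans: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs must have equal length")
        if len(self.seqs) < 2:
            raise AlignmentError(
                f"genus {self.genus_label!r}: need >=2 sequences, "
                f"got {len(self.seqs)}"
            )
        length = len(self.seqs[0])
        if length < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != length:
                raise AlignmentError(
                    f"record {sid!r} has length {len(s)}, expected {length}"
                )
        if not 0 <= self.reference_index < len(self.seqs):
            raise AlignmentError(
                f"reference_index {self.reference_index} out of range"
            )

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    @property
    def reference_id(self) -> str:
        return self.ids[self.reference_index]

    @property
    def reference_seq(self) -> str:
        return self.seqs[self.reference_index]

    def sequence(self, sample_id: str) -> str:
        try:
            return self.seqs[self.ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def ungapped(self, index: int) -> str:
        return self.seqs[index].replace(GAP, "")

    def drop_gap_only_columns(self) -> tuple["GenusAlignment", int]:
        """Return a copy without columns that are gap in every sequence,
        plus the number of columns dropped."""
        keep = [
            i
            for i in range(self.length)
            if any(s[i] != GAP for s in self.seqs)
        ]
        n_dropped = self.length - len(keep)
        if n_dropped == 0:
            return self, 0
        if not keep:
            raise AlignmentError("alignment consists solely of gap columns")
        new_seqs = tuple("".join(s[i] for i in keep) for s in self.seqs)
        return replace(self, seqs=new_seqs), n_dropped


def read_genus_alignment(
    path: str | Path, genus_label: str, reference_id: Optional[str] = None
) -> GenusAlignment:
    """Load one genus's aligned FASTA.

    Gap-only columns are removed (the drop count is logged); record order is
    preserved; the reference defaults to the first record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(
            f"{path}: need >=2 aligned records, got {len(records)}"
        )
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise AlignmentError(
                f"{path}: record {rec.id!r} has length {len(rec.seq)}, "
                f"expected {length}"
            )
    ids = tuple(rec.id for rec in records)
    seqs = []
    for rec in records:
        s = str(rec.seq).upper()
        bad = set(s) - _VALID_CHARS
        if bad:
            raise AlignmentError(
                f"{path}: record {rec.id!r} contains invalid characters "
                f"{sorted(bad)}"
            )
        seqs.append(s)
    if reference_id is None:
        ref_index = 0
    else:
        try:
            ref_index = ids.index(reference_id)
        except ValueError:
            raise AlignmentError(
                f"{path}: reference id {reference_id!r} not among records"
            ) from None
    aln = GenusAlignment(
        genus_label=genus_label,
        ids=ids,
        seqs=tuple(seqs),
        reference_index=ref_index,
    )
    aln, n_dropped = aln.drop_gap_only_columns()
    if n_dropped:
        log.info(
            "%s: dropped %d gap-only column(s) at load", genus_label, n_dropped
        )
    return aln


def write_genus_alignment(aln: GenusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def alignment_to_reference(aln: GenusAlignment, start: int, end: int) -> tuple[int, int]:
    """Map an alignment-coordinate interval to ungapped reference
    coordinates (both 1-based inclusive).

    An interval lying entirely inside a reference gap maps to the zero-width
    position after the preceding reference residue (start == end).
    """
    if not 1 <= start <= end <= aln.length:
        raise CoordinateError(f"interval [{start},{end}] out of range")
    ref = aln.reference_seq
    before = sum(1 for c in ref[: start - 1] if c != GAP)
    inside = sum(1 for c in ref[start - 1 : end] if c != GAP)
    if inside == 0:
        pos = max(before, 1)
        return pos, pos
    return before + 1, before + inside


# ---------------------------------------------------------------------------
# FeatureTable


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str  # gene | exon | intron
    start: int  # 1-based inclusive, ungapped reference coordinates
    end: int
    strand: str = "+"
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"feature {self.name!r}: end {self.end} < start {self.start}"
            )
        if self.kind not in ("gene", "exon", "intron"):
            raise FormatError(f"unsupported feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FeatureTable:
    """Gene / exon / intron annotation of the ungapped reference sequence."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for f in self.features:
            seen.setdefault((f.name, f.kind), []).append((f.start, f.end))
        for (name, kind), ivals in seen.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise FormatError(
                        f"overlapping {kind} intervals for {name!r}: "
                        f"[{s1},{e1}] and [{s2},{e2}]"
                    )

    def of_kind(self, kind: str) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if f.kind == kind)

    @property
    def genes(self) -> tuple[Feature, ...]:
        return self.of_kind("gene")

    def __len__(self) -> int:
        return len(self.features)


def read_features(path: str | Path) -> FeatureTable:
    """Parse genes, exons and introns from a GFF3 file.

    Other feature kinds are ignored (count logged).  The tRNA anticodon is
    read from an ``anticodon=`` attribute when present.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils error paths vary
        raise FormatError(f"{path}: not parseable as GFF3: {exc}") from exc

    features: list[Feature] = []
    n_ignored = 0
    for f in db.all_features(order_by=("start", "end")):
        if f.featuretype not in ("gene", "exon", "intron"):
            n_ignored += 1
            continue
        name = (
            f.attributes.get("Name", [None])[0]
            or f.attributes.get("gene", [None])[0]
            or f.attributes.get("ID", [None])[0]
        )
        if name is None:
            raise FormatError(f"{path}: feature without Name/gene/ID at {f.start}")
        anticodon = f.attributes.get("anticodon", [None])[0]
        if anticodon is not None and len(anticodon) != 3:
            raise FormatError(
                f"{path}: anticodon {anticodon!r} for {name!r} is not a "
                "3-letter RNA string"
            )
        if f.end < f.start:
            raise FormatError(
                f"{path}: feature {name!r} has end {f.end} < start {f.start}"
            )
        features.append(
            Feature(
                name=name,
                kind=f.featuretype,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                anticodon=anticodon,
            )
        )
    if n_ignored:
        log.info("%s: ignored %d feature line(s) of other kinds", path, n_ignored)
    return FeatureTable(features=tuple(features))


def write_features(
    table: FeatureTable, path: str | Path, seqid: str = "ref"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(table.features):
            attrs = [f"ID={f.kind}-{i + 1}", f"Name={f.name}"]
            if f.anticodon:
                attrs.append(f"anticodon={f.anticodon}")
            fh.write(
                f"{seqid}\tcphotspot\t{f.kind}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{';'.join(attrs)}\n"
            )


# ---------------------------------------------------------------------------
# Inversions


@dataclass(frozen=True)
class InversionSet:
    """User-declared inversion intervals, per sample, on that sample's
    ungapped sequence (1-based inclusive)."""

    intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        per_sample: dict[str, list[tuple[int, int]]] = {}
        for sid, s, e in self.intervals:
            if s > e:
                raise FormatError(f"inversion for {sid!r}: end {e} < start {s}")
            per_sample.setdefault(sid, []).append((s, e))
        for sid, ivals in per_sample.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise FormatError(
                        f"overlapping inversions for {sid!r}: "
                        f"[{s1},{e1}] and [{s2},{e2}]"
                    )

    def __len__(self) -> int:
        return len(self.intervals)


def read_inversions(path: str | Path) -> InversionSet:
    """Read a 4-column TSV (sample_id, start, end, note); '#' lines skipped."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: need >=3 columns: {line!r}")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return InversionSet(intervals=tuple(intervals))


def write_inversions(inv: InversionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\tstart\tend\tnote\n")
        for sid, s, e in inv.intervals:
            fh.write(f"{sid}\t{s}\t{e}\t.\n")


def apply_inversions(
    aln: GenusAlignment, inv: InversionSet
) -> tuple[GenusAlignment, int]:
    """Re-orient each declared segment by reverse-complementing its residues
    in place (gap columns keep their positions).

    The paper's procedure separates inversions before diversity statistics so
    a re-oriented segment no longer inflates apparent divergence.  The
    operation is an involution on gap-free segments.  Returns the new
    alignment (with ``inversion_spans`` recorded) and the applied count.
    """
    seqs = [list(s) for s in aln.seqs]
    spans = list(aln.inversion_spans)
    count = 0
    for sid, s, e in inv.intervals:
        try:
            row_idx = aln.ids.index(sid)
        except ValueError:
            raise CoordinateError(f"unknown sample id {sid!r}") from None
        row = aln.seqs[row_idx]
        residue_cols = [i for i, c in enumerate(row) if c != GAP]
        if not 1 <= s <= e <= len(residue_cols):
            raise CoordinateError(
                f"inversion [{s},{e}] outside ungapped length "
                f"{len(residue_cols)} of {sid!r}"
            )
        cols = residue_cols[s - 1 : e]
        segment = "".join(row[c] for c in cols)
        flipped = reverse_complement(segment)
        for c, ch in zip(cols, flipped):
            seqs[row_idx][c] = ch
        spans.append((sid, cols[0] + 1, cols[-1] + 1))
        count += 1
    if count == 0:
        return aln, 0
    new = replace(
        aln,
        seqs=tuple("".join(s) for s in seqs),
        inversion_spans=tuple(spans),
    )
    return new, count


# ---------------------------------------------------------------------------
# BED output


def write_bed(
    intervals: Iterable[tuple[int, int, str]], path: str | Path, chrom: str
) -> None:
    """Write (start, end, name) 1-based inclusive intervals as BED
    (0-based half-open)."""
    with open(path, "w") as fh:
        for start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
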