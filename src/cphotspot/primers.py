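"""Universal primer design from conserved hotspot flanks.

The flanks of a variable locus are searched for maximal runs of columns in
which every supplied sequence carries the same unambiguous residue; primer
candidates are enumerated inside those runs, so every emitted primer matches
every input sequence exactly at its binding site (universality by
construction).  Diagnostics use the basic GC-count melting-temperature
formula Tm = 64.9 + 41*(nGC - 16.4)/L, adequate for primers longer than
13 nt and free of thermodynamic parameter tables; the formula is isolated
in :func:`melting_temperature` and swappable.

Default constraint ranges (length 18-27 nt, GC 0.30-0.75, Tm 50-65 C,
homopolymers <= 4 nt, product 300-2500 bp, pair Tm difference <= 5 C) are
calibrated so that the published chloroplast universal primer sets for
these loci fall inside them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import groupby
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenusAlignment,
    RESIDUES,
    alignment_to_reference,
    reverse_complement,
)
from .scan import encode_alignment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrimerConstraints:
    min_length: int = 18
    max_length: int = 27
    gc_min: float = 0.30
    gc_max: float = 0.75
    tm_min: float = 50.0
    tm_max: float = 65.0
    homopolymer_max: int = 4
    product_min: int = 300
    product_max: int = 2500
    tm_diff_max: float = 5.0
    flank_span: int = 400
    #: cap on how many candidates per flank enter the quadratic pairing
    #: step; the ones whose binding sites lie nearest the locus are kept
    #: (they minimize product length, the secondary ranking key).
    max_candidates_per_side: int = 150


@dataclass(frozen=True)
class PrimerCandidate:
    """One primer candidate; ``sequence`` is written 5'->3' (top strand for
    forward primers, reverse complement of the top strand for reverse)."""

    sequence: str
    orientation: str  # forward | reverse
    ref_start: int  # binding site, ungapped reference, 1-based inclusive
    ref_end: int
    length: int
    gc_fraction: float
    tm: float
    homopolymer_max: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_start: int
    product_end: int
    product_length: int
    tm_difference: float


def melting_temperature(seq: str) -> float:
    """Basic GC-count melting temperature: 64.9 + 41*(nGC - 16.4)/L."""
    s = seq.upper()
    if not s:
        raise ValueError("empty primer sequence")
    if set(s) - RESIDUES:
        raise ValueError(
            f"primer contains non-ACGT characters: {sorted(set(s) - RESIDUES)}"
        )
    n_gc = sum(1 for c in s if c in "GC")
    return 64.9 + 41.0 * (n_gc - 16.4) / len(s)


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return sum(1 for c in s if c in "GC") / len(s)


def max_homopolymer(seq: str) -> int:
    return max(len(list(g)) for _c, g in groupby(seq.upper()))


# ---------------------------------------------------------------------------
# Conserved runs


def conserved_runs(
    aln: GenusAlignment, start: int, end: int, min_length: int = 18
) -> list[tuple[int, int]]:
    """Maximal runs of columns in [start, end] (alignment coordinates) where
    all sequences carry the same unambiguous residue and no gaps; runs
    shorter than ``min_length`` are dropped."""
    start = max(1, start)
    end = min(aln.length, end)
    if start > end:
        return []
    enc = encode_alignment(aln)[:, start - 1 : end]
    conserved = (enc < 4).all(axis=0) & (enc == enc[0]).all(axis=0)
    runs = []
    i = 0
    n = conserved.shape[0]
    while i < n:
        if conserved[i]:
            j = i
            while j + 1 < n and conserved[j + 1]:
                j += 1
            if j - i + 1 >= min_length:
                runs.append((start + i, start + j))
            i = j + 1
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# Candidate enumeration


def enumerate_candidates(
    aln: GenusAlignment,
    run: tuple[int, int],
    orientation: str,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> list[PrimerCandidate]:
    """All primer candidates inside one conserved run, in deterministic
    order (by start, then length).

    Hard filters: length, GC fraction, Tm window, homopolymer length.  The
    3'-G/C-clamp preference is soft: candidates lacking it are flagged
    ``no_gc_clamp`` but kept.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward|reverse, got {orientation!r}")
    c = constraints
    ref_row = aln.reference_seq
    s, e = run
    top = ref_row[s - 1 : e]
    if set(top) - RESIDUES:
        # conserved runs contain unambiguous residues by construction
        raise ValueError("conserved run contains non-residue characters")
    out: list[PrimerCandidate] = []
    run_len = e - s + 1
    # the run is gap-free in every sequence, so reference coordinates are
    # contiguous inside it: map the run start once and offset
    run_ref_start = alignment_to_reference(aln, s, e)[0]
    for a in range(run_len):
        for length in range(c.min_length, c.max_length + 1):
            if a + length > run_len:
                break
            sub = top[a : a + length]
            gc = gc_fraction(sub)
            if not c.gc_min <= gc <= c.gc_max:
                continue
            tm = melting_temperature(sub)
            if not c.tm_min <= tm <= c.tm_max:
                continue
            homo = max_homopolymer(sub)
            if homo > c.homopolymer_max:
                continue
            seq5to3 = sub if orientation == "forward" else reverse_complement(sub)
            flags = () if seq5to3[-1] in "GC" else ("no_gc_clamp",)
            rs, re = run_ref_start + a, run_ref_start + a + length - 1
            out.append(
                PrimerCandidate(
                    sequence=seq5to3,
                    orientation=orientation,
                    ref_start=rs,
                    ref_end=re,
                    length=length,
                    gc_fraction=gc,
                    tm=tm,
                    homopolymer_max=homo,
                    flags=flags,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Pairing


def pair_primers(
    forwards: Sequence[PrimerCandidate],
    reverses: Sequence[PrimerCandidate],
    locus_ref: tuple[int, int],
    constraints: PrimerConstraints = PrimerConstraints(),
) -> list[PrimerPair]:
    """Pairs whose product brackets the entire target locus, within the
    product-length and Tm-difference caps; ranked by (Tm difference, product
    length), deterministically.

    On an empty result, logs the constraint that rejected most combinations.
    """
    c = constraints
    failures: Counter[str] = Counter()
    pairs = []
    for f in forwards:
        for r in reverses:
            if not (f.orientation == "forward" and r.orientation == "reverse"):
                failures["orientation"] += 1
                continue
            if f.ref_end >= r.ref_start:
                failures["orientation"] += 1
                continue
            product_start, product_end = f.ref_start, r.ref_end
            if not (product_start <= locus_ref[0] and locus_ref[1] <= product_end):
                failures["locus_not_contained"] += 1
                continue
            product_length = product_end - product_start + 1
            if not c.product_min <= product_length <= c.product_max:
                failures["product_length"] += 1
                continue
            tm_diff = abs(f.tm - r.tm)
            if tm_diff > c.tm_diff_max:
                failures["tm_difference"] += 1
                continue
            pairs.append(
                PrimerPair(
                    forward=f,
                    reverse=r,
                    product_start=product_start,
                    product_end=product_end,
                    product_length=product_length,
                    tm_difference=tm_diff,
                )
            )
    pairs.sort(
        key=lambda p: (
            p.tm_difference,
            p.product_length,
            p.forward.ref_start,
            p.reverse.ref_start,
        )
    )
    if not pairs and failures:
        worst, n = failures.most_common(1)[0]
        log.warning(
            "no valid primer pair: most frequent failure %r (%d combinations)",
            worst,
            n,
        )
    return pairs


def design_primers(
    aln: GenusAlignment,
    locus: tuple[int, int],
    constraints: PrimerConstraints = PrimerConstraints(),
) -> list[PrimerPair]:
    """End-to-end design for one locus given in alignment coordinates:
    conserved runs in the up/downstream flanks -> candidates -> ranked pairs."""
    c = constraints
    up = (locus[0] - c.flank_span, locus[0] - 1)
    down = (locus[1] + 1, locus[1] + c.flank_span)
    if up[0] < 1 or down[1] > aln.length:
        log.warning(
            "flank of locus [%d,%d] truncated to the alignment bounds",
            locus[0],
            locus[1],
        )
    forwards = []
    for run in conserved_runs(aln, up[0], up[1], c.min_length):
        forwards.extend(enumerate_candidates(aln, run, "forward", c))
    reverses = []
    for run in conserved_runs(aln, down[0], down[1], c.min_length):
        reverses.extend(enumerate_candidates(aln, run, "reverse", c))
    # conserved flanks can yield thousands of near-duplicate candidates;
    # keep the ones nearest the locus on each side (deterministic) so the
    # pairing step stays tractable
    m = c.max_candidates_per_side
    forwards.sort(key=lambda p: (-p.ref_end, p.ref_start))
    reverses.sort(key=lambda p: (p.ref_start, p.ref_end))
    locus_ref = alignment_to_reference(aln, locus[0], locus[1])
    return pair_primers(forwards[:m], reverses[:m], locus_ref, c)


def primer_table(
    pairs_by_locus: dict[str, list[PrimerPair]], top_n: int = 1
) -> pd.DataFrame:
    """Flat table of the top-ranked pair(s) per locus, mirroring the
    published primer-set schema (locus, primer name, sequence 5'->3',
    orientation, Tm, GC%, product length)."""
    rows = []
    for locus, pairs in pairs_by_locus.items():
        for i, p in enumerate(pairs[:top_n]):
            for cand, tag in ((p.forward, "f"), (p.reverse, "r")):
                rows.append(
                    {
                        "locus": locus,
                        "primer": f"{locus}-{tag}" + (f"{i + 1}" if i else ""),
                        "sequence_5to3": cand.sequence.lower(),
                        "orientation": cand.orientation,
                        "ref_start": cand.ref_start,
                        "ref_end": cand.ref_end,
                        "length": cand.length,
                        "tm_C": round(cand.tm, 2),
                        "gc_pct": round(100 * cand.gc_fraction, 1),
                        "product_length": p.product_length,
                        "flags": ";".join(cand.flags),
                    }
                )
    return pd.DataFrame(rows)


def verify_universality(
    aln: GenusAlignment, cand: PrimerCandidate
) -> bool:
    """String-compare the primer's binding site against every ungapped input
    sequence (exact match required)."""
    top = (
        cand.sequence
        if cand.orientation == "forward"
        else reverse_complement(cand.sequence)
    )
    # map the reference-coordinate site into each sequence via the alignment
    ref = aln.reference_seq
    respos = [i for i, ch in enumerate(ref) if ch != "-"]
    cols = respos[cand.ref_start - 1 : cand.ref_end]
    for s in aln.seqs:
        site = "".join(s[c] for c in cols)
        if site != top:
            return False
    return True
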