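"""DnaSP-style sliding-window variability scan.

Per window of the gapped alignment: segregating sites S, nucleotide
diversity per site (pi), the number of retained columns under the chosen
site-deletion policy, and indel/inversion event counts.  Whole-profile
summaries (S_max, mean, sample standard deviation) feed the hotspot
threshold S > mean + k*stdev.

Deletion policies
-----------------
``complete``  — a column is analyzed only if *no* sequence shows a gap or an
ambiguous character there (DnaSP's default treatment of gapped sites).
``pairwise``  — every column is retained; each sequence pair is compared
over the columns where both members carry an unambiguous residue.

Windows are defined on alignment coordinates: the paper scanned the aligned
genomes, and alignment columns are the only coordinate system shared by all
sequences of a genus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoordinateError, GenusAlignment

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 600  # bp, the typical length of a DNA barcode read
DEFAULT_STEP = 50  # bp, fine enough for accurate positioning of hotspots

POLICIES = ("complete", "pairwise")

# Encoding: A,C,G,T -> 0..3; ambiguity/missing -> 4; gap -> 5.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("-")] = 5
_MISSING = 4
_GAP = 5


def encode_alignment(aln: GenusAlignment) -> np.ndarray:
    """Return the alignment as an (n_sequences, length) uint8 code matrix."""
    raw = np.vstack(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in aln.seqs]
    )
    return _CODE[raw]


_encode = encode_alignment


def _check_range(aln: GenusAlignment, start: int, end: int) -> None:
    if not 1 <= start <= end <= aln.length:
        raise CoordinateError(
            f"window [{start},{end}] out of bounds for alignment of length "
            f"{aln.length}"
        )


def _check_policy(policy: str) -> None:
    if policy not in POLICIES:
        raise ValueError(f"unknown deletion policy {policy!r}; use one of {POLICIES}")


@dataclass(frozen=True)
class WindowStat:
    """Statistics of one alignment window (1-based inclusive coordinates)."""

    start: int
    end: int
    S: int
    L_retained: int
    pi: Optional[float]  # None when no sequence pair has analyzable columns
    indel_events: int
    inversion_events: int = 0

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class ScanProfile:
    """Ordered window statistics of one genus plus profile summaries."""

    genus_label: str
    window: int
    step: int
    policy: str
    windows: tuple[WindowStat, ...]
    s_max: int
    s_mean: float
    s_stdev: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "midpoint": [w.midpoint for w in self.windows],
                "S": [w.S for w in self.windows],
                "L_retained": [w.L_retained for w in self.windows],
                "pi": [w.pi for w in self.windows],
                "indel_events": [w.indel_events for w in self.windows],
                "inversion_events": [w.inversion_events for w in self.windows],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# genus={self.genus_label}\n")
            fh.write(
                f"# window={self.window} step={self.step} policy={self.policy}\n"
            )
            fh.write(
                f"# S_max={self.s_max} S_mean={self.s_mean!r} "
                f"S_stdev={self.s_stdev!r}\n"
            )
            self.to_dataframe().to_csv(
                fh, sep="\t", index=False, na_rep="NA", float_format="%.17g"
            )


def read_profile(path: str | Path) -> ScanProfile:
    """Read a profile TSV written by :meth:`ScanProfile.write_tsv`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        for tok in line[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    df = pd.read_csv(
        path, sep="\t", comment="#", na_values="NA",
        float_precision="round_trip",
    )
    windows = tuple(
        WindowStat(
            start=int(r.start),
            end=int(r.end),
            S=int(r.S),
            L_retained=int(r.L_retained),
            pi=None if pd.isna(r.pi) else float(r.pi),
            indel_events=int(r.indel_events),
            inversion_events=int(r.inversion_events),
        )
        for r in df.itertuples()
    )
    return ScanProfile(
        genus_label=meta.get("genus", "?"),
        window=int(meta.get("window", DEFAULT_WINDOW)),
        step=int(meta.get("step", DEFAULT_STEP)),
        policy=meta.get("policy", "complete"),
        windows=windows,
        s_max=int(meta["S_max"]),
        s_mean=float(meta["S_mean"]),
        s_stdev=float(meta["S_stdev"]),
    )


# ---------------------------------------------------------------------------
# Per-window statistics


def retained_columns(
    aln: GenusAlignment, start: int, end: int, policy: str = "complete"
) -> list[int]:
    """1-based columns of [start, end] analyzed under the deletion policy."""
    _check_range(aln, start, end)
    _check_policy(policy)
    if policy == "pairwise":
        return list(range(start, end + 1))
    enc = _encode(aln)[:, start - 1 : end]
    good = (enc < _MISSING).all(axis=0)
    return [start + i for i in np.nonzero(good)[0]]


def segregating_sites(
    aln: GenusAlignment, start: int, end: int, policy: str = "complete"
) -> int:
    """Count retained columns with >=2 distinct residue states among
    non-missing characters."""
    _check_range(aln, start, end)
    _check_policy(policy)
    enc = _encode(aln)[:, start - 1 : end]
    return int(_segregating(enc, policy))


def _segregating(enc: np.ndarray, policy: str) -> int:
    valid = enc < _MISSING
    if policy == "complete":
        cols = valid.all(axis=0)
        sub = enc[:, cols]
        if sub.shape[1] == 0:
            return 0
        return int((sub != sub[0]).any(axis=0).sum())
    # pairwise: per column, >=2 distinct states among valid residues
    lo = enc.min(axis=0, initial=255, where=valid)
    hi = enc.max(axis=0, initial=0, where=valid)
    any_valid = valid.any(axis=0)
    return int(((lo != hi) & any_valid).sum())


def nucleotide_diversity(
    aln: GenusAlignment, start: int, end: int, policy: str = "complete"
) -> Optional[float]:
    """Average per-site proportion of differences over all sequence pairs.

    pi = (2 / (n(n-1))) * sum_{i<j} d_ij / L_ij, where d_ij and L_ij are the
    mismatch and comparable-column counts of pair (i, j) under the deletion
    policy.  Pairs with no comparable columns are skipped and the pair count
    adjusted; if no pair is analyzable the window's pi is None (undefined,
    never reported as 0).
    """
    _check_range(aln, start, end)
    _check_policy(policy)
    if aln.n_sequences < 2:
        raise ValueError("nucleotide diversity requires >=2 sequences")
    enc = _encode(aln)[:, start - 1 : end]
    return _pi(enc, policy)


def _pi(enc: np.ndarray, policy: str) -> Optional[float]:
    n = enc.shape[0]
    valid = enc < _MISSING
    if policy == "complete":
        cols = valid.all(axis=0)
        enc = enc[:, cols]
        valid = valid[:, cols]
    total = 0.0
    n_pairs = 0
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        L_ij = int(both.sum())
        if L_ij == 0:
            continue
        d_ij = int(((enc[i] != enc[j]) & both).sum())
        total += d_ij / L_ij
        n_pairs += 1
    if n_pairs == 0:
        return None
    return total / n_pairs


def gap_run_events(aln: GenusAlignment) -> list[tuple[int, int]]:
    """All indel events of the alignment as sorted (start, end) gap runs.

    An event is a maximal run of gap characters in one sequence; runs with
    identical coordinates in multiple sequences collapse into one event (a
    single historical indel shared by those lineages).
    """
    events: set[tuple[int, int]] = set()
    for s in aln.seqs:
        i = 0
        L = len(s)
        while i < L:
            if s[i] == "-":
                j = i
                while j + 1 < L and s[j + 1] == "-":
                    j += 1
                events.add((i + 1, j + 1))
                i = j + 1
            else:
                i += 1
    return sorted(events)


def indel_events(aln: GenusAlignment, start: int, end: int) -> int:
    """Count indel events whose first gap column lies in [start, end]."""
    _check_range(aln, start, end)
    return sum(1 for s, _e in gap_run_events(aln) if start <= s <= end)


def inversion_events(aln: GenusAlignment, start: int, end: int) -> int:
    """Count separated inversions whose first column lies in [start, end]."""
    _check_range(aln, start, end)
    return sum(1 for _sid, s, _e in aln.inversion_spans if start <= s <= end)


# ---------------------------------------------------------------------------
# Profile scan


def window_starts(length: int, window: int, step: int) -> list[int]:
    """Starts 1, 1+s, 1+2s, ... with last start <= length - window + 1."""
    return list(range(1, length - window + 2, step))


def scan_windows(
    aln: GenusAlignment,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    policy: str = "complete",
) -> ScanProfile:
    """Slide a window of ``window`` bp by ``step`` bp over the alignment and
    compute per-window statistics plus profile summaries.

    A trailing stretch shorter than the window is not scanned (a shrunken
    window would have an incomparable S); the skipped length is logged.
    """
    _check_policy(policy)
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if aln.length < window:
        raise ValueError(
            f"alignment length {aln.length} < window {window}; "
            "lower the window length"
        )
    enc = _encode(aln)
    events = gap_run_events(aln)
    event_starts = np.array([s for s, _ in events], dtype=np.int64)
    inv_starts = np.array(
        sorted(s for _sid, s, _e in aln.inversion_spans), dtype=np.int64
    )
    starts = window_starts(aln.length, window, step)
    trailing = aln.length - (starts[-1] + window - 1)
    if trailing:
        log.info(
            "%s: trailing %d bp shorter than the window not scanned",
            aln.genus_label,
            trailing,
        )
    stats = []
    for start in starts:
        end = start + window - 1
        sub = enc[:, start - 1 : end]
        valid = sub < _MISSING
        if policy == "complete":
            L_ret = int(valid.all(axis=0).sum())
        else:
            L_ret = window
        S = _segregating(sub, policy)
        pi = _pi(sub, policy)
        n_indel = int(
            np.searchsorted(event_starts, end, side="right")
            - np.searchsorted(event_starts, start, side="left")
        )
        n_inv = int(
            np.searchsorted(inv_starts, end, side="right")
            - np.searchsorted(inv_starts, start, side="left")
        )
        stats.append(
            WindowStat(
                start=start,
                end=end,
                S=S,
                L_retained=L_ret,
                pi=pi,
                indel_events=n_indel,
                inversion_events=n_inv,
            )
        )
    s_max, s_mean, s_stdev = summarize_profile(stats)
    return ScanProfile(
        genus_label=aln.genus_label,
        window=window,
        step=step,
        policy=policy,
        windows=tuple(stats),
        s_max=s_max,
        s_mean=s_mean,
        s_stdev=s_stdev,
    )


def summarize_profile(
    windows: Sequence[WindowStat],
) -> tuple[int, float, float]:
    """(S_max, arithmetic mean of S, sample standard deviation of S).

    Sample (n-1 denominator) standard deviation; 0.0 for a single window.
    """
    if not windows:
        raise ValueError("cannot summarize an empty window collection")
    s_values = [w.S for w in windows]
    s_max = max(s_values)
    s_mean = float(np.mean(s_values))
    s_stdev = float(np.std(s_values, ddof=1)) if len(s_values) > 1 else 0.0
    return s_max, s_mean, s_stdev
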