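"""Hotspot-locus detection, annotation-based naming and per-locus reporting.

Windows whose segregating-site count S strictly exceeds mean + k*stdev of
the profile (k = 2 by default) are merged into loci, named from the
reference annotation (gene / "gene intron" / leftGene-rightGene spacer, with
tRNA anticodon suffixes where paralogs require disambiguation, and -a/-b
suffixes when one gene hosts several disjoint loci), and reported with
recomputed per-locus pi and indel/inversion indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io_formats import (
    Feature,
    FeatureTable,
    GenusAlignment,
    alignment_to_reference,
    write_bed,
)
from .scan import (
    ScanProfile,
    WindowStat,
    indel_events,
    inversion_events,
    nucleotide_diversity,
    segregating_sites,
)

log = logging.getLogger(__name__)

CATEGORIES = ("coding", "intron", "intergenic_spacer", "mixed", "control")


@dataclass(frozen=True)
class HotspotLocus:
    """A merged above-threshold region of one genus's alignment."""

    genus_label: str
    start: int  # alignment coordinates, 1-based inclusive
    end: int
    name: str
    category: str
    s_locus: int  # maximum window S inside the locus
    pi_locus: Optional[float]
    indel_events: int
    inversion_events: int
    threshold_used: float
    ref_start: int = 0  # ungapped reference coordinates
    ref_end: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Window selection and merging


def select_windows(profile: ScanProfile, k: float = 2.0) -> list[WindowStat]:
    """Windows with S strictly greater than S_mean + k*S_stdev, in order."""
    if k < 0:
        raise ValueError(f"threshold multiplier k must be >= 0, got {k}")
    cutoff = profile.s_mean + k * profile.s_stdev
    return [w for w in profile.windows if w.S > cutoff]


def merge_windows(
    windows: Sequence[WindowStat], max_gap: int = 50
) -> list[tuple[int, int]]:
    """Fuse overlapping qualifying windows, and windows separated by at most
    ``max_gap`` bp, into sorted non-overlapping intervals.

    ``max_gap`` defaults to one step so that staircase artifacts bridge but
    well-separated sub-loci (the ycf1-a / ycf1-b situation) stay distinct.
    """
    if not windows:
        return []
    ivals = sorted((w.start, w.end) for w in windows)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s - merged[-1][1] - 1 <= max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# Annotation-based naming


@dataclass(frozen=True)
class _GeneModel:
    name: str
    anticodon: Optional[str]
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]


def _gene_models(features: FeatureTable) -> list[_GeneModel]:
    """Group exon/intron features under the gene record containing them.

    A gene without annotated exon structure is treated as entirely exonic.
    A gene with exons but no explicit introns gets the gaps between
    consecutive exons as introns.
    """
    genes = sorted(features.genes, key=lambda f: (f.start, f.end))
    exons = features.of_kind("exon")
    introns = features.of_kind("intron")
    models = []
    for g in genes:
        my_exons = tuple(
            sorted(
                (f.start, f.end)
                for f in exons
                if f.name == g.name and g.start <= f.start and f.end <= g.end
            )
        )
        my_introns = tuple(
            sorted(
                (f.start, f.end)
                for f in introns
                if f.name == g.name and g.start <= f.start and f.end <= g.end
            )
        )
        if my_exons and not my_introns:
            my_introns = tuple(
                (e1 + 1, s2 - 1)
                for (_s1, e1), (s2, _e2) in zip(my_exons, my_exons[1:])
                if s2 > e1 + 1
            )
        if not my_exons:
            my_exons = ((g.start, g.end),)
        models.append(
            _GeneModel(
                name=g.name,
                anticodon=g.anticodon,
                start=g.start,
                end=g.end,
                exons=my_exons,
                introns=my_introns,
            )
        )
    return models


def _display_name(model: _GeneModel, models: Sequence[_GeneModel]) -> str:
    """Gene name, with an anticodon suffix when paralogs share the base name
    with different anticodons (trnS^UGA^ vs trnS^GCU^)."""
    if model.anticodon is None:
        return model.name
    anticodons = {
        m.anticodon for m in models if m.name == model.name and m.anticodon
    }
    if len(anticodons) > 1 or sum(1 for m in models if m.name == model.name) > 1:
        return f"{model.name}^{model.anticodon}^"
    return model.name


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def name_locus(
    interval: tuple[int, int],
    features: FeatureTable,
    aln: GenusAlignment,
) -> tuple[str, str]:
    """Assign (name, category) to an alignment-coordinate interval.

    The interval is mapped to ungapped reference coordinates through the
    reference row's gap structure, then labeled by majority (>=50%) overlap:
    exons of one gene -> coding; one gene's intron -> "<gene> intron"; the
    spacer between two genes -> "left-right"; otherwise mixed, named by the
    dominant feature.
    """
    rs, re = alignment_to_reference(aln, interval[0], interval[1])
    if len(features) == 0:
        log.warning(
            "empty feature table: locus [%d,%d] named by coordinates",
            interval[0],
            interval[1],
        )
        return f"region_{rs}_{re}", "mixed"
    length = re - rs + 1
    models = _gene_models(features)

    # (overlap, name, category) for the three >=50% rules
    contributions: list[tuple[int, str, str]] = []
    # (overlap, name) for the mixed fallback: whole-gene spans vs spacers,
    # so a locus straddling a split (exon/intron) gene is still named for
    # that gene rather than flipping between its flanking spacers
    dominant: list[tuple[int, str]] = []
    for m in models:
        disp = _display_name(m, models)
        exon_ov = sum(_overlap((rs, re), ex) for ex in m.exons)
        if exon_ov:
            contributions.append((exon_ov, disp, "coding"))
        intron_ov = sum(_overlap((rs, re), iv) for iv in m.introns)
        if intron_ov:
            contributions.append((intron_ov, f"{disp} intron", "intron"))
        span_ov = _overlap((rs, re), (m.start, m.end))
        if span_ov:
            if intron_ov > exon_ov:
                dominant.append((span_ov, f"{disp} intron"))
            else:
                dominant.append((span_ov, disp))

    # intergenic segments between consecutive gene spans (genome order)
    spans = sorted(((m.start, m.end, m) for m in models))
    prev_end = 0
    prev_model: Optional[_GeneModel] = None
    segments: list[tuple[int, int, Optional[_GeneModel], Optional[_GeneModel]]] = []
    for s, e, m in spans:
        if s > prev_end + 1:
            segments.append((prev_end + 1, s - 1, prev_model, m))
        prev_end = max(prev_end, e)
        prev_model = m
    ref_len = len(aln.ungapped(aln.reference_index))
    if prev_end < ref_len:
        segments.append((prev_end + 1, ref_len, prev_model, None))
    for s, e, left, right in segments:
        ov = _overlap((rs, re), (s, e))
        if ov:
            ln = _display_name(left, models) if left else "upstream"
            rn = _display_name(right, models) if right else "downstream"
            contributions.append((ov, f"{ln}-{rn}", "intergenic_spacer"))
            dominant.append((ov, f"{ln}-{rn}"))

    if not contributions:
        return f"region_{rs}_{re}", "mixed"
    contributions.sort(key=lambda t: (-t[0], t[1]))
    best_ov, best_name, best_cat = contributions[0]
    if best_ov / length >= 0.5:
        return best_name, best_cat
    dominant.sort(key=lambda t: (-t[0], t[1]))
    return dominant[0][1], "mixed"


def _suffix_duplicates(names: list[str]) -> list[str]:
    """Append -a, -b, ... (in coordinate order) to repeated locus names."""
    counts: dict[str, int] = {}
    for n in names:
        counts[n] = counts.get(n, 0) + 1
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if counts[n] > 1:
            i = seen.get(n, 0)
            seen[n] = i + 1
            out.append(f"{n}-{chr(ord('a') + i)}")
        else:
            out.append(n)
    return out


# ---------------------------------------------------------------------------
# Locus assembly and reporting


def find_hotspot_loci(
    profile: ScanProfile,
    aln: GenusAlignment,
    features: FeatureTable,
    k: float = 2.0,
    max_gap: Optional[int] = None,
) -> list[HotspotLocus]:
    """Threshold, merge, name and score hotspot loci for one genus."""
    if max_gap is None:
        max_gap = profile.step
    qualifying = select_windows(profile, k=k)
    intervals = merge_windows(qualifying, max_gap=max_gap)
    cutoff = profile.s_mean + k * profile.s_stdev
    names = []
    cats = []
    for iv in intervals:
        name, cat = name_locus(iv, features, aln)
        names.append(name)
        cats.append(cat)
    names = _suffix_duplicates(names)
    loci = []
    for (s, e), name, cat in zip(intervals, names, cats):
        s_locus = max(w.S for w in qualifying if s <= w.start and w.end <= e)
        rs, re = alignment_to_reference(aln, s, e)
        loci.append(
            HotspotLocus(
                genus_label=profile.genus_label,
                start=s,
                end=e,
                name=name,
                category=cat,
                s_locus=s_locus,
                pi_locus=nucleotide_diversity(aln, s, e, profile.policy),
                indel_events=indel_events(aln, s, e),
                inversion_events=inversion_events(aln, s, e),
                threshold_used=cutoff,
                ref_start=rs,
                ref_end=re,
            )
        )
    return loci


def locus_report(
    loci: Sequence[HotspotLocus],
    aln: GenusAlignment,
    controls: Optional[Mapping[str, tuple[int, int]]] = None,
    policy: str = "complete",
) -> pd.DataFrame:
    """Per-locus statistics table (pi, indels+inversions indicator I, S,
    length), optionally with named control intervals (e.g. the proposed
    barcodes atpF-atpH, rbcL, rpoB, rpoC1) for side-by-side comparison.

    Control rows carry category "control" and S recomputed over the full
    span (controls have no window-selection history)."""
    rows = []
    for lc in loci:
        rows.append(
            {
                "name": lc.name,
                "category": lc.category,
                "start": lc.start,
                "end": lc.end,
                "length": lc.length,
                "S": lc.s_locus,
                "pi": lc.pi_locus,
                "indel_events": lc.indel_events,
                "inversion_events": lc.inversion_events,
                "I": lc.indel_events + lc.inversion_events,
                "threshold": lc.threshold_used,
            }
        )
    for name, (s, e) in (controls or {}).items():
        rows.append(
            {
                "name": name,
                "category": "control",
                "start": s,
                "end": e,
                "length": e - s + 1,
                "S": segregating_sites(aln, s, e, policy),
                "pi": nucleotide_diversity(aln, s, e, policy),
                "indel_events": indel_events(aln, s, e),
                "inversion_events": inversion_events(aln, s, e),
                "I": indel_events(aln, s, e) + inversion_events(aln, s, e),
                "threshold": float("nan"),
            }
        )
    return pd.DataFrame(rows)


def write_loci_tsv(loci: Sequence[HotspotLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "genus": [lc.genus_label for lc in loci],
            "name": [lc.name for lc in loci],
            "category": [lc.category for lc in loci],
            "start": [lc.start for lc in loci],
            "end": [lc.end for lc in loci],
            "ref_start": [lc.ref_start for lc in loci],
            "ref_end": [lc.ref_end for lc in loci],
            "S_locus": [lc.s_locus for lc in loci],
            "pi": [lc.pi_locus for lc in loci],
            "indel_events": [lc.indel_events for lc in loci],
            "inversion_events": [lc.inversion_events for lc in loci],
            "threshold": [lc.threshold_used for lc in loci],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_loci_tsv(path: str | Path) -> list[HotspotLocus]:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    return [
        HotspotLocus(
            genus_label=str(r.genus),
            start=int(r.start),
            end=int(r.end),
            name=str(r.name),
            category=str(r.category),
            s_locus=int(r.S_locus),
            pi_locus=None if pd.isna(r.pi) else float(r.pi),
            indel_events=int(r.indel_events),
            inversion_events=int(r.inversion_events),
            threshold_used=float(r.threshold),
            ref_start=int(r.ref_start),
            ref_end=int(r.ref_end),
        )
        for r in df.itertuples()
    ]


def write_loci_bed(
    loci: Sequence[HotspotLocus], path: str | Path, chrom: str
) -> None:
    write_bed([(lc.start, lc.end, lc.name) for lc in loci], path, chrom)
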