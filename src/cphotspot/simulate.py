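"""Synthetic congeneric chloroplast-like genome alignments with planted
mutational hotspots, indels, microsatellite stutter, and small inversions,
plus a matching gene/intron/spacer annotation track and a truth table.

Model
-----
An ancestral sequence of length L is drawn uniformly over {A,C,G,T}; each
taxon evolves independently from it on a star phylogeny under Jukes-Cantor
with branch length t_b substitutions/site outside hotspots and f*t_b inside
(per-site substitution probability p = (3/4)(1 - exp(-4t/3)), with a change
landing uniformly on the three other bases — exactly the JC transition
matrix, so divergence between two taxa follows the closed form at total
path length 2*t_b).  Indels are realized as lineage-specific deletions from
the ancestral state (gap runs in one taxon), so the emitted alignment IS
the true alignment in ancestral coordinates and no realignment is needed.
Microsatellites are (AT)n tracts whose repeat number varies per taxon
(taxon-specific deletions of whole AT units).  One taxon carries small
inversions, emitted both applied (reverse-complemented in place) and as a
declaration table so downstream separation can be exercised.

The reference taxon (row 0) receives substitutions but no indels or
inversions, so the annotation's ungapped reference coordinates coincide
with ancestral coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    Feature,
    FeatureTable,
    GenusAlignment,
    InversionSet,
)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated genus.

    Defaults emulate a pair of recently diverged congeners on a ~30 kb
    plastome segment: background divergence 2*0.002 = 0.004 substitutions
    per site between two taxa, six 800 bp hotspots mutating 10x faster,
    a handful of indels and (AT)n tracts, and one small inversion.
    """

    seed: int = 0
    genome_length: int = 30000
    n_taxa: int = 2
    background_branch_length: float = 0.002  # substitutions/site/branch
    hotspot_count: int = 6
    hotspot_length: int = 800
    hotspot_rate_multiplier: float = 10.0
    indel_rate: float = 2e-4  # events/site/branch
    indel_length_mean: float = 4.0  # geometric
    microsat_count: int = 3
    microsat_units: int = 10  # ancestral (AT)n repeat number
    inversion_count: int = 1
    inversion_length: int = 30
    gene_count: int = 40

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ConfigurationError("n_taxa must be >= 2")
        if self.hotspot_rate_multiplier < 1:
            raise ConfigurationError("hotspot_rate_multiplier must be >= 1")
        for name in ("background_branch_length", "indel_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.hotspot_count * self.hotspot_length > self.genome_length // 2:
            raise ConfigurationError(
                "hotspots exceed half the genome; shrink count or length"
            )
        if self.gene_count < 1 or self.genome_length // self.gene_count < 40:
            raise ConfigurationError("gene_count too large for genome_length")


@dataclass(frozen=True)
class SimTruth:
    """Planted events, in ancestral (= alignment = reference) coordinates
    unless noted."""

    hotspot_intervals: tuple[tuple[int, int], ...]
    private_hotspot_intervals: tuple[tuple[int, int], ...]
    indel_events: tuple[tuple[str, int, int], ...]  # alignment coordinates
    inversion_intervals: tuple[tuple[int, int], ...]  # ancestral coordinates
    inversions: InversionSet  # sample-ungapped declaration, ready to separate
    hotspot_substitutions: tuple[int, ...]  # realized, per planted hotspot
    background_substitutions: int

    @property
    def all_hotspots(self) -> tuple[tuple[int, int], ...]:
        return self.hotspot_intervals + self.private_hotspot_intervals

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#kind\tsample\tstart\tend\tinfo\n")
            for (s, e), c in zip(
                self.hotspot_intervals, self.hotspot_substitutions
            ):
                fh.write(f"hotspot\t.\t{s}\t{e}\tsubstitutions={c}\n")
            for s, e in self.private_hotspot_intervals:
                fh.write(f"private_hotspot\t.\t{s}\t{e}\t.\n")
            for sid, s, e in self.indel_events:
                fh.write(f"indel\t{sid}\t{s}\t{e}\t.\n")
            for (sid, s, e), (as_, ae) in zip(
                self.inversions.intervals, self.inversion_intervals
            ):
                fh.write(f"inversion\t{sid}\t{s}\t{e}\tancestral={as_}-{ae}\n")
            fh.write(
                f"background\t.\t.\t.\t"
                f"substitutions={self.background_substitutions}\n"
            )


@dataclass(frozen=True)
class GenomeLayout:
    """Annotation track plus planted-element placement, shared by all taxa
    of a genus (and by all genera of a multi-genus study)."""

    features: FeatureTable
    hotspot_intervals: tuple[tuple[int, int], ...]
    microsat_tracts: tuple[tuple[int, int], ...]
    inversion_sites: tuple[tuple[int, int], ...]


def expected_pairwise_divergence(t_total: float) -> float:
    """Jukes-Cantor expected proportion of differing sites between two
    sequences separated by ``t_total`` substitutions/site of total path:
    (3/4)(1 - exp(-4 t / 3)).  Saturates at 0.75."""
    if t_total < 0:
        raise ValueError(f"t_total must be >= 0, got {t_total}")
    return 0.75 * (1.0 - math.exp(-4.0 * t_total / 3.0))


# ---------------------------------------------------------------------------
# Layout


def _spacer_center(unit: int, unit_len: int, gene_margin: int) -> int:
    """Center of the spacer between unit's gene and the next unit's gene."""
    return (unit + 1) * unit_len - gene_margin // 2


def make_layout(cfg: SimConfig, rng: np.random.Generator) -> GenomeLayout:
    """Tile the genome with named genes separated by spacers and place the
    planted elements.

    Hotspots alternate between genic and intergenic contexts; like the
    hotspots of real plastomes (kb-scale genes such as ycf1/ndhF, wide
    spacers such as rpl32-trnL), their host features are sized to contain
    them: a genic hotspot sits inside a long two-unit gene, an intergenic
    one inside a widened spacer (the following gene is omitted).  Every
    fifth ordinary gene gets a two-exon/one-intron structure; tRNA paralog
    pairs carry anticodon qualifiers.  (AT)n tracts and inversion sites go
    into spacers away from hotspots.
    """
    L, G = cfg.genome_length, cfg.gene_count
    unit = L // G
    margin = max(unit // 5, 20)  # spacer on each side of a gene
    if cfg.hotspot_length > 2 * (unit - margin) - 80:
        raise ConfigurationError(
            "hotspot_length too large for the gene tiling; increase "
            "genome_length or decrease gene_count/hotspot_length"
        )

    # choose host units first: evenly spread, one unit of slack after each
    host_units: dict[int, str] = {}
    for h in range(cfg.hotspot_count):
        j = int(round((h + 0.5) * G / max(cfg.hotspot_count, 1))) - 1
        j = min(max(j, 0), G - 3)
        if j in host_units or j + 1 in host_units:
            raise ConfigurationError(
                "hotspot placement infeasible: host genes collide; reduce "
                "hotspot_count or increase gene_count"
            )
        host_units[j] = "genic" if h % 2 == 0 else "intergenic"

    special = {
        10: ("trnS", "UGA"),
        12: ("trnG", "UCC"),
        20: ("trnS", "GCU"),
        22: ("trnG", "GCC"),
    }
    features: list[Feature] = []
    hotspots: list[tuple[int, int]] = []
    skip_next = False
    for i in range(G):
        if skip_next:
            skip_next = False
            continue
        u0 = i * unit + 1
        context = host_units.get(i)
        name, anticodon = special.get(i, (f"gene{i + 1:03d}", None))
        if context is not None:
            name, anticodon = f"gene{i + 1:03d}", None
        strand = "-" if i % 7 == 3 else "+"
        if context == "genic":
            # long gene spanning two units, hotspot inside it
            gs, ge = u0 + margin, u0 + 2 * unit - margin - 1
            features.append(
                Feature(name=name, kind="gene", start=gs, end=ge,
                        strand=strand)
            )
            slack = (ge - gs + 1 - cfg.hotspot_length) // 2
            center = (gs + ge) // 2 + int(
                rng.integers(-min(margin, slack), min(margin, slack) + 1)
            )
            skip_next = True
        elif context == "intergenic":
            # normal gene, then a widened spacer (next unit's gene omitted)
            gs, ge = u0 + margin, u0 + unit - margin - 1
            features.append(
                Feature(name=name, kind="gene", start=gs, end=ge,
                        strand=strand)
            )
            spacer_mid = (ge + 1 + (i + 2) * unit + margin) // 2
            center = spacer_mid + int(rng.integers(-margin // 2, margin // 2 + 1))
            skip_next = True
        else:
            gs, ge = u0 + margin, u0 + unit - margin - 1
            features.append(
                Feature(name=name, kind="gene", start=gs, end=ge,
                        strand=strand, anticodon=anticodon)
            )
            if i % 5 == 2 and ge - gs > 90 and anticodon is None:
                third = (ge - gs + 1) // 3
                features.append(
                    Feature(name=name, kind="exon", start=gs,
                            end=gs + third - 1, strand=strand)
                )
                features.append(
                    Feature(name=name, kind="exon", start=ge - third + 1,
                            end=ge, strand=strand)
                )
                features.append(
                    Feature(name=name, kind="intron", start=gs + third,
                            end=ge - third, strand=strand)
                )
            continue
        s = max(1, center - cfg.hotspot_length // 2)
        e = min(L, s + cfg.hotspot_length - 1)
        s = e - cfg.hotspot_length + 1
        hotspots.append((s, e))
    for (s1, e1), (s2, e2) in zip(hotspots, hotspots[1:]):
        if s2 <= e1:
            raise ConfigurationError(
                "hotspot placement infeasible: intervals overlap; reduce "
                "hotspot_count or hotspot_length"
            )

    def in_hotspot(s: int, e: int) -> bool:
        return any(s <= he and hs <= e for hs, he in hotspots)

    microsats: list[tuple[int, int]] = []
    tract_len = 2 * cfg.microsat_units
    for k in range(cfg.microsat_count):
        for j in range(k * G // max(cfg.microsat_count, 1), G - 1):
            c = _spacer_center(j, unit, 2 * margin)
            s, e = c - tract_len // 2, c - tract_len // 2 + tract_len - 1
            if not in_hotspot(s, e) and not any(
                s <= ee and ss <= e for ss, ee in microsats
            ):
                microsats.append((s, e))
                break

    inversions: list[tuple[int, int]] = []
    for k in range(cfg.inversion_count):
        for j in range((2 * k + 1) * G // (2 * max(cfg.inversion_count, 1)),
                       G - 1):
            c = _spacer_center(j, unit, 2 * margin) - tract_len
            s, e = c, c + cfg.inversion_length - 1
            if (
                not in_hotspot(s, e)
                and not any(s <= ee and ss <= e for ss, ee in microsats)
                and not any(s <= ee and ss <= e for ss, ee in inversions)
            ):
                inversions.append((s, e))
                break

    return GenomeLayout(
        features=FeatureTable(features=tuple(features)),
        hotspot_intervals=tuple(hotspots),
        microsat_tracts=tuple(microsats),
        inversion_sites=tuple(inversions),
    )


def _private_hotspot_slots(
    cfg: SimConfig, layout: GenomeLayout
) -> list[tuple[int, int]]:
    """Candidate genus-private hotspot intervals, gene-centered, kept well
    clear (>= 1000 bp) of every shared planted element and of each other so
    private loci pick up names distinct from the shared ones."""
    L, G = cfg.genome_length, cfg.gene_count
    unit = L // G
    # wide berth around shared hotspots (their loci spread beyond the
    # planted interval); small planted elements only need non-overlap
    wide = list(layout.hotspot_intervals)
    narrow = list(layout.microsat_tracts) + list(layout.inversion_sites)
    slots: list[tuple[int, int]] = []
    for j in range(1, G - 1):
        center = j * unit + 1 + unit // 2
        s = center - cfg.hotspot_length // 2
        e = s + cfg.hotspot_length - 1
        if s < 1 or e > L:
            continue
        if not all(s > oe + 1000 or e < os_ - 1000 for os_, oe in wide):
            continue
        if not all(s > oe + 100 or e < os_ - 100 for os_, oe in narrow):
            continue
        if all(s > se + 1000 or e < ss - 1000 for ss, se in slots):
            slots.append((s, e))
    return slots


# ---------------------------------------------------------------------------
# Evolution


def simulate_genus(
    cfg: SimConfig,
    genus_label: str = "simgenus",
    layout: Optional[GenomeLayout] = None,
    private_hotspots: tuple[tuple[int, int], ...] = (),
) -> tuple[GenusAlignment, FeatureTable, SimTruth]:
    """Simulate one genus's aligned congeners; same config (and layout)
    gives byte-identical output."""
    rng = np.random.default_rng(cfg.seed)
    if layout is None:
        layout = make_layout(cfg, rng)
    L = cfg.genome_length
    n = cfg.n_taxa
    ids = tuple(f"{genus_label}_sp{i + 1}" for i in range(n))

    anc = rng.integers(0, 4, size=L, dtype=np.uint8)
    # write (AT)n tracts into the ancestor
    for s, e in layout.microsat_tracts:
        tract = np.tile(np.array([0, 3], dtype=np.uint8), (e - s + 2) // 2)
        anc[s - 1 : e] = tract[: e - s + 1]

    rate = np.full(L, cfg.background_branch_length)
    all_hot = tuple(layout.hotspot_intervals) + tuple(private_hotspots)
    for s, e in all_hot:
        rate[s - 1 : e] *= cfg.hotspot_rate_multiplier
    p_sub = 0.75 * (1.0 - np.exp(-4.0 * rate / 3.0))

    rows = np.empty((n, L), dtype=np.uint8)
    for i in range(n):
        r = anc.copy()
        mut = rng.random(L) < p_sub
        k = int(mut.sum())
        if k:
            shift = rng.integers(1, 4, size=k).astype(np.uint8)
            r[mut] = (r[mut] + shift) % 4
        rows[i] = r

    # ---- deletions (gap runs) in non-reference taxa -----------------------
    gap = np.zeros((n, L), dtype=bool)
    occupied: list[tuple[int, int]] = list(layout.microsat_tracts) + list(
        layout.inversion_sites
    )
    indel_events: list[tuple[str, int, int]] = []

    def collides(s: int, e: int) -> bool:
        return any(s <= oe and os_ <= e for os_, oe in occupied)

    for i in range(1, n):
        n_events = int(rng.poisson(cfg.indel_rate * L))
        for _ in range(n_events):
            for _attempt in range(100):
                length = int(rng.geometric(1.0 / cfg.indel_length_mean))
                if length >= L:
                    continue
                s = int(rng.integers(1, L - length + 2))
                e = s + length - 1
                if not collides(s, e):
                    break
            else:  # pragma: no cover - pathological densities only
                continue
            gap[i, s - 1 : e] = True
            occupied.append((s, e))
            indel_events.append((ids[i], s, e))

    # microsatellite stutter: delete 0..4 whole AT units from the tract end
    for s, e in layout.microsat_tracts:
        for i in range(1, n):
            k = int(rng.integers(0, 5))
            if k:
                ds = e - 2 * k + 1
                gap[i, ds - 1 : e] = True
                indel_events.append((ids[i], ds, e))

    # ---- inversions in taxon 1 -------------------------------------------
    inv_sample = ids[1]
    inv_decl: list[tuple[str, int, int]] = []
    inv_ancestral: list[tuple[int, int]] = []
    for s, e in layout.inversion_sites[: cfg.inversion_count]:
        seg = rows[1, s - 1 : e]
        rows[1, s - 1 : e] = (3 - seg)[::-1]  # reverse complement in codes
        gaps_before = int(gap[1, : s - 1].sum())
        inv_decl.append((inv_sample, s - gaps_before, e - gaps_before))
        inv_ancestral.append((s, e))

    # ---- realized substitution counts ------------------------------------
    differs = (rows != anc[None, :]).any(axis=0)
    hot_mask = np.zeros(L, dtype=bool)
    hotspot_subs = []
    for s, e in layout.hotspot_intervals:
        hotspot_subs.append(int(differs[s - 1 : e].sum()))
        hot_mask[s - 1 : e] = True
    for s, e in private_hotspots:
        hot_mask[s - 1 : e] = True
    background_subs = int(differs[~hot_mask].sum())

    # ---- emit -------------------------------------------------------------
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = []
    for i in range(n):
        chars = lut[rows[i]].copy()
        chars[gap[i]] = ord("-")
        seqs.append(chars.tobytes().decode("ascii"))

    aln = GenusAlignment(
        genus_label=genus_label,
        ids=ids,
        seqs=tuple(seqs),
        reference_index=0,
    )
    truth = SimTruth(
        hotspot_intervals=tuple(layout.hotspot_intervals),
        private_hotspot_intervals=tuple(private_hotspots),
        indel_events=tuple(sorted(indel_events)),
        inversion_intervals=tuple(inv_ancestral),
        inversions=InversionSet(intervals=tuple(inv_decl)),
        hotspot_substitutions=tuple(hotspot_subs),
        background_substitutions=background_subs,
    )
    return aln, layout.features, truth


def simulate_study(
    cfg: SimConfig,
    n_genera: int = 3,
    seed: Optional[int] = None,
    private_hotspot_count: int = 0,
    genus_labels: Optional[Sequence[str]] = None,
) -> dict[str, tuple[GenusAlignment, FeatureTable, SimTruth]]:
    """Simulate several genera sharing one genome layout (hence one set of
    named planted hotspots) plus optional genus-private hotspots, as in a
    multi-genus marker-discovery study."""
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_genera + 1)
    layout_rng = np.random.default_rng(children[0])
    layout = make_layout(cfg, layout_rng)
    slots = _private_hotspot_slots(cfg, layout)
    if private_hotspot_count * n_genera > len(slots):
        raise ConfigurationError(
            f"only {len(slots)} private-hotspot slots available for "
            f"{private_hotspot_count} x {n_genera} genera"
        )
    labels = list(genus_labels or (f"genus{i + 1}" for i in range(n_genera)))
    out = {}
    for i, label in enumerate(labels):
        genus_rng = np.random.default_rng(children[i + 1])
        genus_seed = int(genus_rng.integers(0, 2**31 - 1))
        # round-robin over well-separated slots: each genus's private
        # hotspots are disjoint from (and named differently to) every
        # other genus's
        private = tuple(
            slots[i + k * n_genera] for k in range(private_hotspot_count)
        )
        cfg_g = replace(cfg, seed=genus_seed)
        out[label] = simulate_genus(
            cfg_g, genus_label=label, layout=layout, private_hotspots=private
        )
    return out
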