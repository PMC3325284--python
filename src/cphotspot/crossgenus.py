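"""Cross-genus intersection of named hotspot loci.

Plastome coordinates are not comparable across genera, so locus identity is
by annotation-derived name (anticodon-aware).  Loci present in fewer than
``min_genera`` genera (3 by default) are excluded, and the retained loci are
ranked by breadth (genus count) and then by mean nucleotide diversity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hotspots import HotspotLocus, _suffix_duplicates

log = logging.getLogger(__name__)

DEFAULT_MIN_GENERA = 3


@dataclass(frozen=True)
class SharedLocusTable:
    """Locus-by-genus presence/pi matrix (NaN marks absence)."""

    pi: pd.DataFrame  # rows: locus names, columns: genus labels
    min_genera: int = DEFAULT_MIN_GENERA

    @property
    def genus_count(self) -> pd.Series:
        return self.pi.notna().sum(axis=1)

    @property
    def mean_pi(self) -> pd.Series:
        return self.pi.mean(axis=1)

    def __len__(self) -> int:
        return len(self.pi)

    def write_tsv(self, path: str | Path) -> None:
        out = self.pi.copy()
        out.insert(0, "genus_count", self.genus_count)
        out["mean_pi"] = self.mean_pi
        out.to_csv(path, sep="\t", index_label="locus", na_rep="NA")


def intersect_loci(
    loci_by_genus: Mapping[str, Sequence[HotspotLocus]],
    min_genera: int = DEFAULT_MIN_GENERA,
) -> SharedLocusTable:
    """Build the shared-locus table from per-genus locus collections.

    Duplicate locus names within one genus are disambiguated by -a/-b
    suffixing (with a warning); intersection is by exact name.
    """
    if len(loci_by_genus) < 2:
        raise ValueError("cross-genus intersection needs >=2 genera")
    columns: dict[str, dict[str, float]] = {}
    for genus, loci in loci_by_genus.items():
        names = [lc.name for lc in loci]
        if len(set(names)) != len(names):
            log.warning(
                "genus %s: duplicate locus names disambiguated by suffixing",
                genus,
            )
            names = _suffix_duplicates(names)
        columns[genus] = {
            n: (np.nan if lc.pi_locus is None else lc.pi_locus)
            for n, lc in zip(names, loci)
        }
    all_names = sorted({n for col in columns.values() for n in col})
    df = pd.DataFrame(
        {
            genus: [col.get(n, np.nan) for n in all_names]
            for genus, col in columns.items()
        },
        index=all_names,
    )
    return SharedLocusTable(pi=df, min_genera=min_genera)


def retain_shared(
    table: SharedLocusTable, m: int = DEFAULT_MIN_GENERA
) -> SharedLocusTable:
    """Keep loci present in at least ``m`` genera."""
    if m < 1:
        raise ValueError(f"min_genera must be >= 1, got {m}")
    keep = table.genus_count >= m
    return SharedLocusTable(pi=table.pi.loc[keep], min_genera=m)


def cumulative_breakdown(table: SharedLocusTable) -> dict[int, int]:
    """Number of loci shared by >= m genera for every m from 1 to the
    number of genera (the 47/29/23/11/10/5-style breakdown)."""
    counts = table.genus_count
    return {
        m: int((counts >= m).sum()) for m in range(1, table.pi.shape[1] + 1)
    }


def rank_loci(table: SharedLocusTable) -> pd.DataFrame:
    """Rank retained loci by genus count (desc), then mean pi (desc), ties
    broken lexicographically by name; stable and deterministic."""
    df = pd.DataFrame(
        {
            "locus": table.pi.index,
            "genus_count": table.genus_count.values,
            "mean_pi": table.mean_pi.values,
        }
    )
    df = df.sort_values(
        by=["genus_count", "mean_pi", "locus"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def write_breakdown_json(
    table: SharedLocusTable, path: str | Path
) -> dict[int, int]:
    breakdown = cumulative_breakdown(table)
    with open(path, "w") as fh:
        json.dump(
            {
                "n_genera": table.pi.shape[1],
                "min_genera": table.min_genera,
                "loci_shared_by_at_least_m_genera": {
                    str(m): c for m, c in breakdown.items()
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return breakdown
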