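import numpy as np
import pytest

from cphotspot.hotspots import (
    HotspotLocus,
    find_hotspot_loci,
    locus_report,
    merge_windows,
    name_locus,
    read_loci_tsv,
    select_windows,
    write_loci_tsv,
)
from cphotspot.io_formats import Feature, FeatureTable, apply_inversions
from cphotspot.scan import ScanProfile, WindowStat, scan_windows
from cphotspot.simulate import SimConfig, simulate_genus
from conftest import make_aln, random_alignment
import oracles


def profile_from_s(s_values, s_mean=None, s_stdev=None, step=50, window=600):
    """Build a ScanProfile with given per-window S (and optionally pinned
    summary statistics, e.g. printed ones)."""
    windows = tuple(
        WindowStat(start=1 + i * step, end=i * step + window, S=int(s),
                   L_retained=window, pi=s / window, indel_events=0)
        for i, s in enumerate(s_values)
    )
    arr = np.array(s_values, dtype=float)
    return ScanProfile(
        genus_label="toy", window=window, step=step, policy="complete",
        windows=windows,
        s_max=int(arr.max()),
        s_mean=float(arr.mean()) if s_mean is None else s_mean,
        s_stdev=(float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)
        if s_stdev is None else s_stdev,
    )


class TestSelectWindows:
    def test_printed_genus_summary_gives_expected_cutoff(self):
        """With the published per-genus summary (mean 9.67, stdev 9.00 for
        the Aethionema pair) the k=2 cutoff is 27.67: S=28 qualifies and
        S=27 does not."""
        prof = profile_from_s([27, 28, 5], s_mean=9.67, s_stdev=9.00)
        chosen = select_windows(prof, k=2)
        assert [w.S for w in chosen] == [28]
        assert prof.s_mean + 2 * prof.s_stdev == pytest.approx(27.67)

    def test_constant_profile_selects_nothing(self):
        """Strict inequality: stdev 0 means no window exceeds the mean."""
        prof = profile_from_s([4, 4, 4, 4])
        assert select_windows(prof, k=2) == []

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            select_windows(profile_from_s([1, 2, 3]), k=-1)

    def test_matches_filter_oracle_and_nested_in_k(self, rng):
        s = rng.integers(0, 60, size=200).tolist()
        prof = profile_from_s(s)
        selected = {}
        for k in (1, 2, 3):
            chosen = select_windows(prof, k=k)
            cutoff = prof.s_mean + k * prof.s_stdev
            assert chosen == [w for w in prof.windows if w.S > cutoff]
            selected[k] = {w.start for w in chosen}
        assert selected[3] <= selected[2] <= selected[1]


class TestMergeWindows:
    def test_overlapping_windows_fuse(self):
        prof = profile_from_s([10, 10])
        assert merge_windows(prof.windows, max_gap=50) == [(1, 650)]

    def test_disjoint_windows_stay_separate(self):
        ws = [WindowStat(1, 600, 5, 600, 0.0, 0),
              WindowStat(2000, 2600, 5, 601, 0.0, 0)]
        assert merge_windows(ws, max_gap=50) == [(1, 600), (2000, 2600)]

    def test_matches_union_oracle(self, rng):
        for _ in range(10):
            starts = sorted(rng.integers(1, 5000, size=50).tolist())
            ws = [WindowStat(s, s + 99, 1, 100, 0.0, 0) for s in starts]
            got = merge_windows(ws, max_gap=30)
            want = oracles.interval_union([(s, s + 99) for s in starts], 30)
            assert got == want


FEATURES = FeatureTable(
    features=(
        Feature(name="trnH", kind="gene", start=1, end=74, strand="-"),
        Feature(name="psbA", kind="gene", start=500, end=1561),
        Feature(name="ndhA", kind="gene", start=2000, end=3100),
        Feature(name="ndhA", kind="exon", start=2000, end=2540),
        Feature(name="ndhA", kind="exon", start=3080, end=3100),
        Feature(name="ndhA", kind="intron", start=2541, end=3079),
        Feature(name="trnS", kind="gene", start=3500, end=3590,
                anticodon="UGA"),
        Feature(name="trnG", kind="gene", start=3900, end=3970,
                anticodon="UCC"),
        Feature(name="trnS", kind="gene", start=4800, end=4890,
                anticodon="GCU"),
        Feature(name="trnG", kind="gene", start=5200, end=5270,
                anticodon="GCC"),
        Feature(name="ycf1", kind="gene", start=6000, end=11500),
    )
)


def flat_aln(length=12000):
    return make_aln("A" * length, "A" * length)


class TestNameLocus:
    def test_interval_inside_intron(self):
        name, cat = name_locus((2600, 3000), FEATURES, flat_aln())
        assert (name, cat) == ("ndhA intron", "intron")

    def test_intergenic_spacer_between_named_genes(self):
        name, cat = name_locus((100, 450), FEATURES, flat_aln())
        assert (name, cat) == ("trnH-psbA", "intergenic_spacer")

    def test_coding_region(self):
        name, cat = name_locus((600, 1400), FEATURES, flat_aln())
        assert (name, cat) == ("psbA", "coding")

    def test_trna_names_carry_anticodon_when_ambiguous(self):
        # spacer between trnS(UGA) and trnG(UCC): trnS occurs twice with
        # different anticodons, so both flanks get suffixed
        name, cat = name_locus((3600, 3880), FEATURES, flat_aln())
        assert cat == "intergenic_spacer"
        assert name == "trnS^UGA^-trnG^UCC^"

    def test_empty_feature_table_names_by_coordinates(self):
        name, cat = name_locus((10, 90), FeatureTable(features=()), flat_aln())
        assert cat == "mixed" and name.startswith("region_")

    def test_two_loci_in_one_gene_get_ab_suffixes(self):
        """Two disjoint hotspot regions inside one long gene come out as
        <gene>-a and <gene>-b in coordinate order."""
        s_values = [0] * 230
        # windows land inside ycf1 [6000, 11500]: starts 1 + i*50
        for i in (125, 126):   # windows near 6250..6950
            s_values[i] = 50
        for i in (195, 196):   # windows near 9750..10450
            s_values[i] = 50
        prof = profile_from_s(s_values)
        aln = flat_aln(len(s_values) * 50 + 550)
        loci = find_hotspot_loci(prof, aln, FEATURES, k=2)
        names = [lc.name for lc in loci]
        assert names == ["ycf1-a", "ycf1-b"]
        assert [lc.category for lc in loci] == ["coding", "coding"]


class TestFindLociAndReport:
    def test_single_window_locus_pi_equals_window_pi(self, rng):
        aln = random_alignment(rng, n_seqs=2, length=2000, gap_frac=0.0,
                               ambig_frac=0.0, diverge=0.02)
        # plant one divergent patch so exactly one region qualifies
        s = list(aln.seqs[1])
        for i in range(900, 1000):
            s[i] = "A" if aln.seqs[0][i] != "A" else "C"
        aln = make_aln(aln.seqs[0], "".join(s))
        prof = scan_windows(aln, window=200, step=200)  # disjoint windows
        loci = find_hotspot_loci(prof, aln, FeatureTable(features=()), k=2,
                                 max_gap=0)
        assert len(loci) >= 1
        for lc in loci:
            w = next(w for w in prof.windows if w.start == lc.start)
            assert lc.pi_locus == pytest.approx(w.pi, abs=1e-12)
            assert lc.s_locus == w.S

    def test_simulated_hotspot_pi_exceeds_background(self, sim_pair):
        aln, features, truth = sim_pair
        aln, _ = apply_inversions(aln, truth.inversions)
        prof = scan_windows(aln)
        loci = find_hotspot_loci(prof, aln, features)
        assert loci, "no hotspot loci detected at study conditions"
        bg_pi = [w.pi for w in prof.windows
                 if w.pi is not None
                 and not any(w.start <= he and hs <= w.end
                             for hs, he in truth.all_hotspots)]
        genome_bg = sum(bg_pi) / len(bg_pi)
        for lc in loci:
            assert lc.pi_locus > genome_bg

    def test_identical_locus_reports_zero_pi_and_I(self):
        aln = make_aln("ACGT" * 300, "ACGT" * 300)
        lc = HotspotLocus(genus_label="toy", start=1, end=600, name="x",
                          category="mixed", s_locus=0, pi_locus=0.0,
                          indel_events=0, inversion_events=0,
                          threshold_used=1.0)
        df = locus_report([lc], aln, controls={"rbcL": (601, 1200)})
        assert df.loc[df.name == "x", "I"].item() == 0
        ctrl = df[df.category == "control"].iloc[0]
        assert ctrl["pi"] == 0.0 and ctrl["S"] == 0

    def test_loci_tsv_roundtrip(self, tmp_path, sim_pair):
        aln, features, truth = sim_pair
        prof = scan_windows(aln)
        loci = find_hotspot_loci(prof, aln, features)
        p = tmp_path / "loci.tsv"
        write_loci_tsv(loci, p)
        back = read_loci_tsv(p)
        assert [(l.name, l.start, l.end) for l in back] == [
            (l.name, l.start, l.end) for l in loci]

    def test_raising_k_never_adds_loci(self, sim_pair):
        aln, features, truth = sim_pair
        prof = scan_windows(aln)
        spans = {}
        for k in (1.0, 2.0, 3.0):
            loci = find_hotspot_loci(prof, aln, features, k=k)
            spans[k] = [(l.start, l.end) for l in loci]
        # every k=3 locus is covered by some k=2 locus, and so on
        for hi, lo in ((3.0, 2.0), (2.0, 1.0)):
            for s, e in spans[hi]:
                assert any(s2 <= s and e <= e2 for s2, e2 in spans[lo])
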