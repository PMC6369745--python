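"""Mitotype quantification, predominance, lateral transfer, elements."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_obs
from dictycross.crossovers import HaplotypeBlock
from dictycross.layout import GenomeLayout
from dictycross.organelles import (MitotypeProfile, classify_predominance,
                                   cohort_table, cosegregation_scan,
                                   detect_lateral, element_genotype,
                                   mitotype_fractions, plasmid_presence)


def _mito_obs(counts_by_parent, depth_per_site=100, pid="x"):
    """One site per (parent, alt_count) pair."""
    rows = []
    for i, (parent, n_alt) in enumerate(counts_by_parent):
        rows.append((pid, "mt", 100 * (i + 1), "mito", parent,
                     depth_per_site, n_alt, depth_per_site - n_alt,
                     None))
    return make_obs(rows)


def _profile(fracs, parents=("P1", "P2")):
    counts = {p: int(1000 * f) for p, f in zip(parents, fracs)}
    depths = {p: 1000 for p in parents}
    return MitotypeProfile(progeny_id="x", counts=counts, depths=depths,
                           n_sites=len(parents), mean_depth=1000.0)


class TestMitotypeFractions:
    def test_simple_arithmetic(self):
        obs = _mito_obs([("P1", 95), ("P2", 5)])
        prof = mitotype_fractions(obs, ["P1", "P2"])
        assert prof.fractions["P1"] == pytest.approx(0.95)
        assert prof.fractions["P2"] == pytest.approx(0.05)

    def test_single_mitotype_noise_free_is_exactly_one(self):
        obs = _mito_obs([("P1", 100), ("P1", 100), ("P2", 0)])
        prof = mitotype_fractions(obs, ["P1", "P2"])
        assert prof.fractions["P1"] == 1.0
        assert prof.fractions["P2"] == 0.0

    def test_zero_depth_flagged_undefined(self):
        prof = mitotype_fractions(make_obs([]), ["P1", "P2"])
        assert prof.undefined
        assert np.isnan(list(prof.fractions.values())).all()

    def test_fractions_sum_to_one_and_site_order_invariant(self, rng):
        pairs = [("P1", int(rng.integers(0, 100))) for _ in range(20)] + \
                [("P2", int(rng.integers(0, 100))) for _ in range(30)]
        obs = _mito_obs(pairs)
        prof = mitotype_fractions(obs, ["P1", "P2"])
        assert sum(prof.fractions.values()) == pytest.approx(1.0)
        shuffled = obs.sample(frac=1.0, random_state=0)
        prof2 = mitotype_fractions(shuffled, ["P1", "P2"])
        assert prof.fractions == prof2.fractions

    def test_estimator_insensitive_to_site_imbalance(self, rng):
        # 80 sites for P1, 20 for P2, true fractions (0.7, 0.3)
        pairs = [("P1", int(rng.binomial(100, 0.7))) for _ in range(80)] + \
                [("P2", int(rng.binomial(100, 0.3))) for _ in range(20)]
        prof = mitotype_fractions(_mito_obs(pairs), ["P1", "P2"])
        assert prof.fractions["P2"] == pytest.approx(0.3, abs=0.03)


class TestClassifyPredominance:
    @pytest.mark.parametrize("fracs, expected", [
        ((1.0, 0.0), "predominant(P1)"),
        ((0.5, 0.5), "near-equal"),
        ((0.6, 0.4), "near-equal"),      # boundary: max <= t_equal
        ((0.7, 0.3), "mixed"),
        ((0.8, 0.2), "predominant(P1)"),  # boundary: max >= t_pred
    ])
    def test_boundary_enumeration(self, fracs, expected):
        assert classify_predominance(_profile(fracs)) == expected

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            classify_predominance(_profile((0.5, 0.5)), t_pred=0.5,
                                  t_equal=0.6)

    def test_monotone_in_max_fraction(self):
        order = {"near-equal": 0, "mixed": 1, "predominant(P1)": 2}
        prev = -1
        for top in np.linspace(0.5, 1.0, 26):
            cls = classify_predominance(_profile((top, 1 - top)))
            assert order[cls] >= prev
            prev = order[cls]


class TestDetectLateral:
    def test_absent_third_not_flagged(self):
        prof = _profile((0.6, 0.4, 0.0), parents=("P1", "P2", "P3"))
        flag, p = detect_lateral(prof, "P3", noise_floor=0.006)
        assert flag is False and p == 1.0

    def test_full_third_flagged_with_tiny_tail(self):
        counts = {"P1": 0, "P2": 0, "P3": 40}
        depths = {"P1": 40, "P2": 40, "P3": 40}
        prof = MitotypeProfile("x", counts, depths, 3, 40.0)
        flag, p = detect_lateral(prof, "P3", noise_floor=0.006)
        assert flag is True and p < 1e-10

    def test_no_third_sites_indeterminate(self):
        prof = _profile((0.6, 0.4), parents=("P1", "P2"))
        flag, p = detect_lateral(prof, "P3", noise_floor=0.006)
        assert flag is None


class TestCohortTable:
    def test_all_one_parent(self):
        profiles = [_profile((0.95, 0.05)) for _ in range(6)]
        out = cohort_table(profiles, ["P1", "P2"])
        assert out["predominant_counts"] == {"P1": 6, "P2": 0}
        assert out["n_not_predominant"] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_table([], ["P1", "P2"])

    def test_mixed_cohort_counts(self):
        profiles = ([_profile((0.9, 0.1)) for _ in range(4)]
                    + [_profile((0.15, 0.85)) for _ in range(2)]
                    + [_profile((0.55, 0.45))])
        out = cohort_table(profiles, ["P1", "P2"])
        assert out["predominant_counts"] == {"P1": 4, "P2": 2}
        assert out["n_not_predominant"] == 1


class TestElementGenotype:
    def _obs(self, n_alt, depth=100):
        return make_obs([("x", "rDNA", 100, "element", "P1", depth, n_alt,
                          depth - n_alt, None)])

    def test_clean_uniparental(self):
        out = element_genotype(self._obs(100), "rDNA", ["P1", "P2"])
        assert out.iloc[0]["genotype"] == "P1"
        assert out.iloc[0]["fraction"] == 1.0
        assert bool(out.iloc[0]["uniparental"])

    def test_ref_majority_resolves_to_other_parent(self):
        out = element_genotype(self._obs(2), "rDNA", ["P1", "P2"])
        assert out.iloc[0]["genotype"] == "P2"

    def test_tie_unresolved(self):
        out = element_genotype(self._obs(50), "rDNA", ["P1", "P2"])
        assert out.iloc[0]["genotype"] == "unresolved"


class TestCosegregationScan:
    def _layout(self):
        return GenomeLayout(chromosomes=(("c1", 10_000),))

    def _blocks(self, pid, segments):
        # segments: list of (parent, first_pos, last_pos)
        return {(pid, "c1"): [
            HaplotypeBlock("c1", par, first, last, 5, 0)
            for par, first, last in segments]}

    def _scan(self, genos, per_progeny_segments, positions):
        bm = {}
        for pid, segs in per_progeny_segments.items():
            bm.update(self._blocks(pid, segs))
        return cosegregation_scan(genos, bm, self._layout(),
                                  {"c1": np.array(positions)})

    def test_matching_locus_reported(self):
        genos = {"a": "P1", "b": "P1", "c": "P2", "d": "P2"}
        segs = {
            "a": [("P1", 0, 4000), ("P2", 5000, 9000)],
            "b": [("P1", 0, 9000)],
            "c": [("P2", 0, 9000)],
            "d": [("P2", 0, 2000), ("P1", 3000, 5000), ("P2", 6000, 9000)],
        }
        res = self._scan(genos, segs, [1000, 2000, 7000, 8000])
        direct = res.intervals[res.intervals["phase"] == "direct"]
        # sites 1000/2000 match: a=P1,b=P1,c=P2,d=P2 == genotypes
        assert len(direct) == 1
        assert direct.iloc[0]["start"] == 0
        assert direct.iloc[0]["end"] == 7000  # bounded by contradiction
        assert direct.iloc[0]["n_sites"] == 2
        assert not res.uninformative

    def test_anti_matching_locus_excluded(self):
        genos = {"a": "P1", "b": "P2", "c": "P1", "d": "P2"}
        segs = {p: [(g, 0, 9000)] for p, g in
                zip("abcd", ["P1", "P2", "P2", "P1"])}
        res = self._scan(genos, segs, [1000, 5000])
        assert len(res.intervals) == 0

    def test_all_same_genotype_degenerate_flagged(self):
        genos = {"a": "P1", "b": "P1"}
        segs = {"a": [("P1", 0, 9000)], "b": [("P2", 0, 9000)]}
        res = self._scan(genos, segs, [1000])
        assert res.uninformative

    def test_fewer_than_two_progeny_rejected(self):
        with pytest.raises(ValueError):
            self._scan({"a": "P1"}, {"a": [("P1", 0, 9000)]}, [1000])

    def test_matches_brute_force_on_random_patterns(self, rng):
        """Intervals equal an exhaustive all-site check: a maximal reported
        interval covers exactly the supporting sites between two
        contradicting sites."""
        genos = {p: rng.choice(["P1", "P2"]) for p in "abcdef"}
        positions = np.arange(1, 21) * 400
        # random per-progeny haplotype step functions (known everywhere)
        haps = {p: rng.choice(["P1", "P2"], size=len(positions))
                for p in genos}
        segs = {}
        for p, h in haps.items():
            blocks = []
            for i, lab in enumerate(h):
                blocks.append((lab, positions[i], positions[i]))
            segs[p] = blocks
        res = self._scan(genos, segs, positions.tolist())
        swap = {"P1": "P2", "P2": "P1"}
        for phase, mapping in (("direct", None), ("swapped", swap)):
            match = np.array([
                all(haps[p][i] == (genos[p] if mapping is None
                                   else mapping[genos[p]]) for p in genos)
                for i in range(len(positions))])
            got = res.intervals[res.intervals["phase"] == phase]
            # brute force: maximal runs of matching sites
            runs = []
            i = 0
            while i < len(match):
                if match[i]:
                    j = i
                    while j + 1 < len(match) and match[j + 1]:
                        j += 1
                    runs.append((i, j))
                    i = j + 1
                else:
                    i += 1
            assert len(got) == len(runs)
            for (_, row), (i, j) in zip(got.iterrows(), runs):
                assert row["n_sites"] == j - i + 1
                # bounds exclude the neighbouring contradicting sites
                lo = 0 if i == 0 else positions[i - 1] + 1
                hi = 10_000 if j == len(match) - 1 else positions[j + 1]
                assert (row["start"], row["end"]) == (lo, hi)


class TestPlasmidPresence:
    def _coverage(self, plasmid_depth):
        rows = [("s", "c1", 20.0), ("s", "c2", 22.0),
                ("s", "plasmid", plasmid_depth)]
        return pd.DataFrame(rows, columns=["sample", "contig", "mean_depth"])

    def _layout(self):
        return GenomeLayout(chromosomes=(("c1", 1000), ("c2", 1000)),
                            extra_contigs=(("plasmid", 100),))

    @pytest.mark.parametrize("depth, present", [
        (0.0, False), (21.0, True), (0.2, False), (2.0, True)])
    def test_threshold_calls(self, depth, present):
        out = plasmid_presence(self._coverage(depth), "plasmid",
                               self._layout())
        assert bool(out.iloc[0]["present"]) is present

    def test_missing_contig_raises(self):
        cov = pd.DataFrame([("s", "c1", 20.0)],
                           columns=["sample", "contig", "mean_depth"])
        with pytest.raises(ValueError):
            plasmid_presence(cov, "plasmid", self._layout())
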