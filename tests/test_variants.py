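"""VCF ingestion, diagnostic-site filters, origin calls, bins, third-parent scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_obs
from dictycross.layout import GenomeLayout
from dictycross.simulate import SimConfig, simulate_meiosis, simulate_parents, \
    simulate_reads
from dictycross.variants import (InputError, SiteFilters, assign_origins,
                                 estimate_false_call_rate,
                                 scan_third_parent, select_diagnostic_sites,
                                 tally_bins)


def _write_vcf(path, records, samples, contigs=(("c1", 1_000_000),)):
    """Minimal hand-built multi-sample VCF.

    Each record: (chrom, pos0, ref, alt, {sample: (gt, dp, gq, ad)}).
    """
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs:
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="g">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">')
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for chrom, pos0, ref, alt, fmt in records:
            rec = vf.new_record(contig=chrom, start=pos0, alleles=(ref, alt))
            for s in samples:
                gt, dp, gq, ad = fmt[s]
                rec.samples[s]["GT"] = gt
                if dp is not None:
                    rec.samples[s]["DP"] = dp
                if gq is not None:
                    rec.samples[s]["GQ"] = gq
                if ad is not None:
                    rec.samples[s]["AD"] = ad
            vf.write(rec)


def _parent_fmt(gt_a, gt_b, dp=30, gq=99):
    return {"PA": ((gt_a,), dp, gq, None), "PB": ((gt_b,), dp, gq, None)}


class TestSelectDiagnosticSites:
    def test_depth_filter_retains_exactly_passing_sites(self, tmp_path):
        # 1,000 informative sites, 100 with parent depth 5 (< 10) -> 900 kept
        records = []
        for i in range(1000):
            dp = 5 if i < 100 else 30
            records.append(("c1", 10 * i + 1, "A", "T",
                            {"PA": ((0,), dp, 99, None),
                             "PB": ((1,), 30, 99, None)}))
        path = tmp_path / "x.vcf"
        _write_vcf(path, records, ["PA", "PB"])
        lay = GenomeLayout(chromosomes=(("c1", 1_000_000),))
        sites = select_diagnostic_sites(str(path), ["PA", "PB"], lay)
        assert len(sites) == 900

    def test_uninformative_het_indel_and_masked_excluded(self, tmp_path):
        records = [
            ("c1", 100, "A", "T", _parent_fmt(0, 0)),    # all identical
            ("c1", 200, "A", "T",
             {"PA": ((0, 1), 30, 99, None), "PB": ((1,), 30, 99, None)}),
            ("c1", 300, "A", "AT", _parent_fmt(0, 1)),   # indel
            ("c1", 400, "A", "T", _parent_fmt(0, 1)),    # good
            ("c1", 500_000, "G", "C", _parent_fmt(1, 0)),  # masked below
        ]
        path = tmp_path / "x.vcf"
        _write_vcf(path, records, ["PA", "PB"])
        lay = GenomeLayout(chromosomes=(("c1", 1_000_000),),
                           masks=(("c1", 400_000, 600_000),))
        sites = select_diagnostic_sites(str(path), ["PA", "PB"], lay)
        assert sites["pos"].tolist() == [400]
        assert sites["diag_parent"].tolist() == ["PB"]

    def test_three_way_info_class(self, tmp_path):
        fmt3 = lambda a, b, c: {  # noqa: E731
            "PA": ((a,), 30, 99, None), "PB": ((b,), 30, 99, None),
            "PC": ((c,), 30, 99, None)}
        records = [
            ("c1", 100, "A", "T", fmt3(0, 0, 1)),  # marks PC via ALT
            ("c1", 200, "A", "T", fmt3(0, 1, 1)),  # marks PA via REF
            ("c1", 300, "A", "T", fmt3(1, 0, 1)),  # marks PB via REF
        ]
        path = tmp_path / "x.vcf"
        _write_vcf(path, records, ["PA", "PB", "PC"])
        lay = GenomeLayout(chromosomes=(("c1", 1_000_000),))
        sites = select_diagnostic_sites(str(path), ["PA", "PB", "PC"], lay)
        assert sites["diag_parent"].tolist() == ["PC", "PA", "PB"]

    def test_missing_parent_sample_raises(self, tmp_path):
        path = tmp_path / "x.vcf"
        _write_vcf(path, [("c1", 100, "A", "T", _parent_fmt(0, 1))],
                   ["PA", "PB"])
        lay = GenomeLayout(chromosomes=(("c1", 1_000_000),))
        with pytest.raises(InputError):
            select_diagnostic_sites(str(path), ["PA", "PZ"], lay)

    def test_record_order_does_not_matter(self, tmp_path):
        rng = np.random.default_rng(0)
        records = [("c1", int(p), "A", "T", _parent_fmt(0, 1))
                   for p in rng.choice(10_000, size=50, replace=False)]
        lay = GenomeLayout(chromosomes=(("c1", 1_000_000),))
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        _write_vcf(a, records, ["PA", "PB"])
        _write_vcf(b, records[::-1], ["PA", "PB"])
        sa = select_diagnostic_sites(str(a), ["PA", "PB"], lay)
        sb = select_diagnostic_sites(str(b), ["PA", "PB"], lay)
        pd.testing.assert_frame_equal(sa, sb)


class TestAssignOrigins:
    def _fixture(self, tmp_path):
        records = [
            # site diagnostic for PB (ALT); progeny X supports ALT, Y ties
            ("c1", 100, "A", "T",
             {**_parent_fmt(0, 1),
              "X": ((1,), 20, 99, (0, 20)), "Y": ((0,), 20, 99, (10, 10))}),
            # site diagnostic for PA (ALT); X has REF majority -> PB
            ("c1", 200, "G", "C",
             {**_parent_fmt(1, 0),
              "X": ((0,), 18, 99, (17, 1)), "Y": ((None,), None, None, None)}),
        ]
        path = tmp_path / "x.vcf"
        _write_vcf(path, records, ["PA", "PB", "X", "Y"])
        lay = GenomeLayout(chromosomes=(("c1", 1_000_000),))
        sites = select_diagnostic_sites(str(path), ["PA", "PB"], lay)
        return path, sites

    def test_majority_tie_and_missing(self, tmp_path):
        path, sites = self._fixture(tmp_path)
        obs = assign_origins(str(path), sites, ["X", "Y"], ("PA", "PB"))
        x = obs[obs["progeny"] == "X"].set_index("pos")
        assert x.loc[100, "origin_call"] == "PB"
        assert x.loc[200, "origin_call"] == "PB"
        y = obs[obs["progeny"] == "Y"]
        assert y["origin_call"].tolist() == ["ambiguous"]  # tie at site 100
        assert 200 not in y["pos"].tolist()                # no coverage

    def test_missing_progeny_sample_raises(self, tmp_path):
        path, sites = self._fixture(tmp_path)
        with pytest.raises(InputError):
            assign_origins(str(path), sites, ["Z"], ("PA", "PB"))

    def test_read_error_rate_reflected_in_depth1_calls(self):
        # at depth 1 a call is wrong with probability eps exactly
        lay = GenomeLayout(chromosomes=(("c1", 2_000_000),))
        cfg = SimConfig(eps=0.01, depth_lambda=1.0, snp_density=5e-3)
        rng = np.random.default_rng(4)
        sites = simulate_parents(lay, cfg, rng)
        truth = simulate_meiosis(lay, cfg, rng)
        obs = simulate_reads(truth, sites, cfg, rng)
        d1 = obs[(obs["depth"] == 1) & (obs["contig_type"] == "nuclear")]
        exp = truth.origin_at("c1", d1["pos"].to_numpy(), cfg.nuclear_parents)
        n_disc = int((d1["origin_call"].to_numpy() != exp).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], len(d1), 0.01)
        assert lo <= n_disc <= hi


class TestTallyBins:
    def _layout(self):
        return GenomeLayout(chromosomes=(("c1", 130_000),))

    def test_hand_enumerated_bins(self):
        obs = make_obs([
            ("x", "c1", 10_000, "nuclear", "PA", 10, 10, 0, "PA"),
            ("x", "c1", 60_000, "nuclear", "PA", 10, 10, 0, "PA"),
            ("x", "c1", 120_000, "nuclear", "PB", 10, 10, 0, "PB"),
        ])
        bins = tally_bins(obs, self._layout(), parents=["PA", "PB"])
        assert len(bins) == 3
        assert bins["count_PA"].tolist() == [1, 1, 0]
        assert bins["count_PB"].tolist() == [0, 0, 1]
        assert bins["bin_end"].tolist() == [50_000, 100_000, 130_000]

    def test_boundary_site_falls_in_right_bin(self):
        obs = make_obs([("x", "c1", 50_000, "nuclear", "PA", 5, 5, 0, "PA")])
        bins = tally_bins(obs, self._layout(), parents=["PA"])
        assert bins["count_PA"].tolist() == [0, 1, 0]

    def test_empty_observations_give_zero_tallies(self):
        obs = make_obs([])
        bins = tally_bins(obs, self._layout(), parents=["PA", "PB"])
        assert len(bins) == 3
        assert (bins["count_PA"] == 0).all() and (bins["count_PB"] == 0).all()

    def test_counts_plus_ambiguous_conserve_total(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(200):
            call = rng.choice(["PA", "PB", "ambiguous"])
            rows.append(("x", "c1", int(rng.integers(0, 130_000)), "nuclear",
                         "PA", 5, 3, 2, call))
        obs = make_obs(rows)
        bins = tally_bins(obs, self._layout(), parents=["PA", "PB"])
        total = (bins["count_PA"] + bins["count_PB"] + bins["ambiguous"]).sum()
        assert total == 200

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            tally_bins(make_obs([]), self._layout(), bin_size=0)


class TestThirdParentScan:
    def _null_obs(self, rng, n_sites=10_000, eps_site=0.002, block=0.0):
        rows = []
        n_third = int(n_sites * block)
        for i in range(n_sites):
            if i < n_third:
                call = "P3"
            else:
                call = "P3" if rng.random() < eps_site else "ambiguous"
            rows.append(("x", "c1", i * 100, "nuclear", "P3", 20,
                         20 if call == "P3" else 0,
                         0 if call == "P3" else 20, call))
        return make_obs(rows)

    def test_zero_support_gives_tail_probability_one(self):
        obs = make_obs([("x", "c1", 100, "nuclear", "P3", 20, 0, 20,
                         "ambiguous")])
        rep = scan_third_parent(obs, "P3", eps_est=0.002)
        assert rep["verdict"].tolist() == ["no-evidence"]
        assert rep["p_raw"].tolist() == [1.0]

    def test_null_progeny_not_flagged(self, rng):
        rep = scan_third_parent(self._null_obs(rng), "P3", eps_est=0.002)
        assert rep["verdict"].tolist() == ["no-evidence"]

    def test_true_contribution_flagged(self, rng):
        rep = scan_third_parent(self._null_obs(rng, block=0.05), "P3",
                                eps_est=0.002)
        assert rep["verdict"].tolist() == ["candidate-lateral-nuclear-transfer"]
        assert rep["p_raw"].iloc[0] < 1e-6

    def test_no_third_sites_raises(self):
        obs = make_obs([("x", "c1", 100, "nuclear", "P1", 20, 20, 0, "P1")])
        with pytest.raises(InputError):
            scan_third_parent(obs, "P3", eps_est=0.002)

    def test_invalid_eps(self, rng):
        with pytest.raises(ValueError):
            scan_third_parent(self._null_obs(rng, 100), "P3", eps_est=1.0)


def test_false_call_rate_estimated_from_discordance():
    lay = GenomeLayout(chromosomes=(("c1", 2_000_000),))
    cfg = SimConfig(eps=0.2, depth_lambda=1.0, snp_density=2e-3,
                    n_macrocysts=5, xo_rate=0.5, seed=8)
    from dictycross.simulate import simulate_cross
    res = simulate_cross(lay, cfg)
    est = estimate_false_call_rate(res.obs, cfg.nuclear_parents)
    # site-level discordance is below the read-level eps because multi-read
    # sites vote errors down, but stays the same order of magnitude
    assert 0.05 < est < 0.2
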