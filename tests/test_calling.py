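"""Bayes factor, posterior, prior construction and cohort calling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shearwater import (
    CallConfig,
    PriorTrack,
    bayes_factor,
    bf_cutoff_for_posterior,
    betabinom_pmf,
    build_mutation_histogram,
    build_prior_track,
    call_variants,
    posterior_null,
    score_hypotheses,
    write_vcf,
)


def direct_bayes_factor(xf, nf, xr, nr, muf, mur, rho):
    """Linear-space oracle: the three numerator pmf products over the denominator."""
    nuf = xf / nf if nf else 0.0
    nur = xr / nr if nr else 0.0
    lf_mu = betabinom_pmf(xf, nf, mu=muf, rho=rho)
    lr_mu = betabinom_pmf(xr, nr, mu=mur, rho=rho)
    lf_nu = betabinom_pmf(xf, nf, mu=nuf, rho=rho)
    lr_nu = betabinom_pmf(xr, nr, mu=nur, rho=rho)
    num = lf_mu * lr_nu + lf_nu * lr_mu - lf_mu * lr_mu
    return max(num, 0.0) / (lf_nu * lr_nu)


def _bf(xf, nf, xr, nr, muf, mur, rho, **kw):
    nuf = xf / nf if nf else 0.0
    nur = xr / nr if nr else 0.0
    return bayes_factor(xf, nf, xr, nr, muf, mur, nuf, nur, rho, **kw)


class TestBayesFactor:
    @given(
        xf=st.integers(0, 30), xr=st.integers(0, 30),
        extra_f=st.integers(0, 100), extra_r=st.integers(0, 100),
        muf=st.floats(1e-5, 0.2), mur=st.floats(1e-5, 0.2),
        rho=st.floats(1e-6, 0.3),
    )
    def test_log_space_matches_direct_evaluation(self, xf, xr, extra_f, extra_r, muf, mur, rho):
        nf, nr = xf + extra_f, xr + extra_r
        ours = _bf(xf, nf, xr, nr, muf, mur, rho)
        oracle = direct_bayes_factor(xf, nf, xr, nr, muf, mur, rho)
        if oracle > 1e-290:  # oracle underflows in linear space below this
            assert ours == pytest.approx(oracle, rel=1e-9)

    def test_strand_swap_symmetry_is_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            nf, nr = rng.integers(1, 200, size=2)
            xf, xr = rng.integers(0, nf + 1), rng.integers(0, nr + 1)
            muf, mur = rng.uniform(1e-4, 0.1, size=2)
            rho = rng.uniform(1e-6, 0.2)
            assert _bf(xf, nf, xr, nr, muf, mur, rho) == _bf(xr, nr, xf, nf, mur, muf, rho)

    def test_no_variant_reads_example(self):
        # x=0 on both strands: mild evidence for the null, near 1
        ours = _bf(0, 100, 0, 100, 1e-3, 1e-3, 1e-6)
        oracle = direct_bayes_factor(0, 100, 0, 100, 1e-3, 1e-3, 1e-6)
        assert ours == pytest.approx(oracle, rel=1e-12)
        assert 0.8 < ours <= 1.0

    def test_overwhelming_variant_evidence(self):
        assert _bf(30, 100, 30, 100, 1e-3, 1e-3, 1e-4) < 1e-10

    def test_zero_coverage_means_no_evidence(self):
        assert _bf(0, 0, 0, 0, 1e-3, 1e-3, 1e-4) == 1.0

    def test_uncovered_strand_neutralizes_or_null(self):
        # plenty of forward reads but no reverse coverage: BF stays 1
        assert _bf(50, 100, 0, 0, 1e-3, 1e-3, 1e-4) == pytest.approx(1.0)

    def test_monotone_in_symmetric_counts(self):
        bfs = [_bf(x, 200, x, 200, 1e-3, 1e-3, 1e-4) for x in range(0, 40, 2)]
        assert all(b1 >= b2 for b1, b2 in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("total", [8, 16, 32])
    def test_single_strand_signal_stays_null(self, total):
        # all reads on one strand score no better than an even split
        lopsided = _bf(total, 200, 0, 200, 1e-3, 1e-3, 1e-4)
        even = _bf(total // 2, 200, total // 2, 200, 1e-3, 1e-3, 1e-4)
        assert lopsided >= even
        assert lopsided > 0.5  # single-strand artifact absorbed by the OR null

    def test_additive_numerator_upper_bounds_inclusion_exclusion(self):
        ie = _bf(5, 100, 4, 100, 1e-3, 1e-3, 1e-4)
        add = _bf(5, 100, 4, 100, 1e-3, 1e-3, 1e-4, numerator="additive")
        assert add >= ie

    def test_strand_agnostic_mode_pools_counts(self):
        ours = _bf(10, 100, 0, 100, 1e-3, 1e-3, 1e-4, strand_mode="agnostic")
        pooled = betabinom_pmf(10, 200, mu=1e-3, rho=1e-4) / betabinom_pmf(
            10, 200, mu=0.05, rho=1e-4
        )
        assert ours == pytest.approx(pooled, rel=1e-9)
        # and the single-strand signal is no longer absorbed
        assert ours < _bf(10, 100, 0, 100, 1e-3, 1e-3, 1e-4)


class TestPosterior:
    def test_symmetric_case(self):
        assert posterior_null(1.0, 0.5) == 0.5

    def test_zero_bayes_factor(self):
        assert posterior_null(0.0, 0.3) == 0.0

    def test_direct_substitution(self):
        assert posterior_null(1.0, 0.1) == pytest.approx(0.9)

    def test_monotone_in_bf_and_pi(self):
        bfs = np.logspace(-6, 2, 30)
        post = posterior_null(bfs, 0.01)
        assert np.all(np.diff(post) > 0)
        pis = np.linspace(0.01, 0.99, 30)
        post = posterior_null(0.5, pis)
        assert np.all(np.diff(post) < 0)

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            posterior_null(1.0, 0.0)
        with pytest.raises(ValueError):
            posterior_null(1.0, 1.0)

    def test_bf_cutoff_inverts_posterior(self):
        for pi in (1e-4, 0.05, 0.5):
            for p0 in (0.1, 0.5, 0.9):
                cut = bf_cutoff_for_posterior(p0, pi)
                assert posterior_null(cut, pi) == pytest.approx(p0)
        assert bf_cutoff_for_posterior(0.5, 0.05) == pytest.approx(0.05 / 0.95)


class TestPrior:
    def test_single_record_histogram(self):
        h = build_mutation_histogram([((("chr1", 5)), "T", 4)])
        assert h == {(("chr1", 5), "T"): 1.0}

    def test_normalization(self):
        h = build_mutation_histogram(
            [(("chr1", 5), "T", 3), (("chr1", 9), "C", 1)]
        )
        assert h[(("chr1", 5), "T")] == 0.75
        assert h[(("chr1", 9), "C")] == 0.25
        assert sum(h.values()) == pytest.approx(1.0)

    def test_duplicates_summed_before_normalizing(self):
        h = build_mutation_histogram(
            [(("chr1", 5), "T", 1), (("chr1", 5), "T", 2), (("chr1", 9), "C", 1)]
        )
        assert h[(("chr1", 5), "T")] == 0.75

    def test_empty_records_give_empty_map(self):
        assert build_mutation_histogram([]) == {}

    def test_prior_is_gene_prob_times_histogram(self):
        track = build_prior_track({"G1": {(("chr1", 5), "T"): 0.75}}, 0.01, pi0=1e-4)
        assert track.get("chr1", 5, "T") == pytest.approx(0.0075)

    def test_uncatalogued_site_falls_back_to_pi0(self):
        track = build_prior_track({}, 0.01, pi0=1e-4)
        assert track.get("chr1", 123, "G") == 1e-4

    def test_full_histogram_mass(self):
        track = build_prior_track({"G1": {(("chr1", 5), "T"): 1.0}}, 0.5)
        assert track.get("chr1", 5, "T") == pytest.approx(0.5)

    def test_missing_gene_probability_is_an_error(self):
        with pytest.raises(ValueError, match="gene probability"):
            build_prior_track({"G1": {(("chr1", 5), "T"): 1.0}}, {"G2": 0.1})


class TestCallVariants:
    def test_all_zero_cohort_yields_no_calls(self, make_tensor):
        tensor = make_tensor(10, [("chr1", 3), ("chr1", 7)], ["A", "C"])
        assert call_variants(tensor, config=CallConfig()) == []

    def test_single_implanted_variant_is_the_only_call(self, make_tensor):
        # 50 samples, coverage 200/strand; sample 7 has 20 variant reads per strand
        entries = {(7, 1, "T", 0): 20, (7, 1, "T", 1): 20}
        tensor = make_tensor(50, [("chr1", 3), ("chr1", 7)], ["A", "A"], entries, base_coverage=200)
        calls = call_variants(tensor, config=CallConfig(posterior_cutoff=0.5, pi0=1e-4))
        assert [(c.sample, c.pos, c.alt) for c in calls] == [("S7", 7, "T")]
        assert calls[0].vaf_combined == pytest.approx(0.1)
        assert calls[0].posterior_m0 <= 0.5

    def test_polymorphism_carriers_each_called_then_excludable(self, make_tensor):
        # variant at VAF 0.5 in 40 of 50 samples: carriers fall out of every
        # reference set, so each carrier is still called...
        entries = {}
        for i in range(40):
            entries[(i, 0, "G", 0)] = 50
            entries[(i, 0, "G", 1)] = 50
        tensor = make_tensor(50, [("chr1", 9)], ["A"], entries, base_coverage=100)
        config = CallConfig(vaf_threshold=0.1)
        calls = call_variants(tensor, config=config)
        assert {c.sample for c in calls} == {f"S{i}" for i in range(40)}
        # the aggregate control stays clean (carriers excluded); only the
        # target's own reads pool into its error-rate estimate
        assert all(c.mu_fwd < 0.1 for c in calls)
        # ... and dropped only by the explicit exclusion list
        excl = config.with_overrides(exclusion=frozenset({("chr1", 9, "G")}))
        assert call_variants(tensor, config=excl) == []

    def test_empty_reference_set_suppresses_test(self, make_tensor, caplog):
        # two samples, the other one is a high-VAF carrier: J(i) is empty
        entries = {(1, 0, "C", 0): 50, (1, 0, "C", 1): 50, (0, 0, "C", 0): 30, (0, 0, "C", 1): 30}
        tensor = make_tensor(2, [("chr1", 0)], ["A"], entries, base_coverage=100)
        with caplog.at_level("INFO", logger="shearwater.calling"):
            calls = call_variants(tensor, config=CallConfig())
        assert calls == []
        assert any("empty reference set" in rec.message for rec in caplog.records)

    def test_score_hypotheses_matches_call_path(self, make_tensor):
        entries = {(7, 1, "T", 0): 20, (7, 1, "T", 1): 20}
        tensor = make_tensor(50, [("chr1", 3), ("chr1", 7)], ["A", "A"], entries, base_coverage=200)
        calls = call_variants(tensor, config=CallConfig())
        bf = score_hypotheses(tensor, [(7, 1, 3)], CallConfig())  # allele index 3 = T
        assert bf[0] == pytest.approx(calls[0].bf, rel=1e-12)

    def test_deterministic_vcf_bytes(self, make_tensor, tmp_path, reference_fasta):
        entries = {(3, 0, "C", 0): 15, (3, 0, "C", 1): 18}
        tensor = make_tensor(20, [("chr1", 12)], ["A"], entries, base_coverage=150)
        paths = []
        for tag in ("a", "b"):
            calls = call_variants(tensor, config=CallConfig())
            out = tmp_path / f"{tag}.vcf"
            write_vcf(calls, reference_fasta, out, sample_ids=tensor.sample_ids)
            paths.append(out)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_posterior_consistent_with_emitted_fields(self, make_tensor, tmp_path, reference_fasta):
        entries = {(3, 0, "C", 0): 15, (3, 0, "C", 1): 18, (9, 1, "G", 0): 30, (9, 1, "G", 1): 25}
        tensor = make_tensor(
            20, [("chr1", 12), ("chr1", 14)], ["A", "G"], entries, base_coverage=150
        )
        # site 2 ref is G, so the G entries implant a T-site variant instead
        calls = call_variants(tensor, config=CallConfig())
        out = tmp_path / "calls.vcf"
        write_vcf(calls, reference_fasta, out, sample_ids=tensor.sample_ids)
        checked = 0
        for line in out.read_text().splitlines():
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            pi = float(fields[7].split("PI=")[1].split(";")[0])
            keys = fields[8].split(":")
            for sample_field in fields[9:]:
                if sample_field == ".":
                    continue
                values = dict(zip(keys, sample_field.split(":")))
                recomputed = posterior_null(float(values["BF"]), pi)
                assert recomputed == pytest.approx(float(values["PM0"]), abs=1e-9)
                checked += 1
        assert checked == len(calls) > 0

    def test_missing_reference_alleles_rejected(self, make_tensor):
        tensor = make_tensor(3, [("chr1", 0)], ["A"])
        tensor.ref_allele = None
        with pytest.raises(ValueError, match="reference"):
            call_variants(tensor)
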