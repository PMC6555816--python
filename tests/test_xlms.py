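"""Cross-link validation, consensus and sector-classification tests."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taushield import xlms
from taushield.xlms import (
    ConsensusLink,
    FilterCriteria,
    SectorScheme,
    SelfLinkError,
    apply_filters,
    assign_sector,
    build_consensus,
    canonicalize,
    compute_dss_masses,
    differential_retention,
    export_contact_matrix,
    summarize_sectors,
)


class TestDssMasses:
    def test_printed_constants_from_atomic_masses(self):
        m = compute_dss_masses()
        assert m.pair_delta_da == pytest.approx(12.075321, abs=1e-5)
        assert m.light_shift_da == pytest.approx(138.068080, abs=1e-5)
        assert m.monolink_hydrolyzed_da == pytest.approx(156.078644, abs=1e-5)

    def test_hydrolyzed_monolink_adds_one_water(self):
        m = compute_dss_masses()
        assert m.monolink_hydrolyzed_da - m.light_shift_da == pytest.approx(
            18.010565, abs=1e-5
        )


class TestCanonicalize:
    def test_swaps_residues_and_peptide_fields(self, make_record):
        rec = make_record(res_a=321, res_b=280, pep_len_a=8, pep_len_b=12,
                          frag_ions_a=4, frag_ions_b=7, contig_frags_a=3,
                          contig_frags_b=6)
        out = canonicalize(rec)
        assert (out.res_a, out.res_b) == (280, 321)
        assert (out.pep_len_a, out.pep_len_b) == (12, 8)
        assert (out.frag_ions_a, out.frag_ions_b) == (7, 4)
        assert (out.contig_frags_a, out.contig_frags_b) == (6, 3)

    def test_identity_on_ordered_input(self, make_record):
        rec = make_record(res_a=280, res_b=321)
        assert canonicalize(rec) == rec

    def test_self_link_rejected(self, make_record):
        with pytest.raises(SelfLinkError):
            canonicalize(make_record(res_a=280, res_b=280))


def _brute_force_pass(r, c):
    """Independent predicate-by-predicate evaluation of the filter rules."""
    checks = [
        r.score > c.min_score,
        c.ppm_min <= r.mass_error_ppm <= c.ppm_max,
        r.tic_pct > c.min_tic_pct,
        r.pep_len_a >= c.min_pep_len,
        r.pep_len_b >= c.min_pep_len,
        (r.frag_ions_a >= c.min_frag_ions) or (r.contig_frags_a >= c.min_contig_frags),
        (r.frag_ions_b >= c.min_frag_ions) or (r.contig_frags_b >= c.min_contig_frags),
    ]
    return all(checks)


def _random_records(rng, n, make_record):
    recs = []
    for i in range(n):
        recs.append(
            make_record(
                replicate_id=f"rep{rng.integers(1, 6)}",
                res_a=int(rng.integers(244, 310)),
                res_b=int(rng.integers(311, 381)),
                score=float(rng.uniform(15, 45)),
                mass_error_ppm=float(rng.uniform(-5, 6)),
                tic_pct=float(rng.uniform(0, 40)),
                pep_len_a=int(rng.integers(3, 20)),
                pep_len_b=int(rng.integers(3, 20)),
                frag_ions_a=int(rng.integers(0, 9)),
                frag_ions_b=int(rng.integers(0, 9)),
                contig_frags_a=int(rng.integers(0, 7)),
                contig_frags_b=int(rng.integers(0, 7)),
                nseen=int(rng.integers(1, 10)),
            )
        )
    return recs


class TestFilters:
    def test_all_passing_record_retained(self, make_record):
        assert apply_filters([make_record()]) == [make_record()]

    @pytest.mark.parametrize(
        "overrides",
        [
            {"score": 24.9},
            {"score": 25.0},  # strict >
            {"mass_error_ppm": -2.3},
            {"mass_error_ppm": 3.9},
            {"tic_pct": 10.0},  # strict >
            {"pep_len_a": 5},
            {"pep_len_b": 5},
            {"frag_ions_a": 3, "contig_frags_a": 2},
            {"frag_ions_b": 3, "contig_frags_b": 2},
        ],
    )
    def test_each_criterion_rejects(self, make_record, overrides):
        assert apply_filters([make_record(**overrides)]) == []

    @pytest.mark.parametrize(
        "overrides",
        [
            {"mass_error_ppm": -2.2},  # ppm bounds inclusive
            {"mass_error_ppm": 3.8},
            {"pep_len_a": 6},  # length >= 6
            {"frag_ions_a": 3, "contig_frags_a": 3},  # 3 contiguous rescue
            {"frag_ions_a": 4, "contig_frags_a": 0},
        ],
    )
    def test_boundary_values_retained(self, make_record, overrides):
        assert len(apply_filters([make_record(**overrides)])) == 1

    def test_empty_input(self):
        assert apply_filters([]) == []

    def test_matches_brute_force_oracle_on_random_records(self, rng, make_record):
        recs = _random_records(rng, 50, make_record)
        crit = FilterCriteria()
        expected = [r for r in recs if _brute_force_pass(r, crit)]
        assert apply_filters(recs, crit) == expected

    def test_idempotent(self, rng, make_record):
        recs = _random_records(rng, 50, make_record)
        once = apply_filters(recs)
        assert apply_filters(once) == once

    @given(
        d_score=st.floats(0, 10),
        d_tic=st.floats(0, 10),
        d_len=st.integers(0, 4),
        shrink=st.floats(0, 2),
    )
    @settings(max_examples=25, deadline=None)
    def test_raising_thresholds_is_monotone(self, d_score, d_tic, d_len, shrink):
        rng = np.random.default_rng(7)
        recs = []
        for _ in range(60):
            recs.append(
                xlms.CrossLinkRecord(
                    replicate_id="r", condition="WT", temperature_c=37.0,
                    res_a=int(rng.integers(244, 310)), res_b=int(rng.integers(311, 381)),
                    score=float(rng.uniform(15, 45)),
                    mass_error_ppm=float(rng.uniform(-5, 6)),
                    tic_pct=float(rng.uniform(0, 40)),
                    pep_len_a=int(rng.integers(3, 20)), pep_len_b=int(rng.integers(3, 20)),
                    frag_ions_a=int(rng.integers(0, 9)), frag_ions_b=int(rng.integers(0, 9)),
                    contig_frags_a=int(rng.integers(0, 7)), contig_frags_b=int(rng.integers(0, 7)),
                    nseen=1,
                )
            )
        base = FilterCriteria()
        stricter = FilterCriteria(
            min_score=base.min_score + d_score,
            ppm_min=base.ppm_min + shrink / 2,
            ppm_max=base.ppm_max - shrink / 2,
            min_tic_pct=base.min_tic_pct + d_tic,
            min_pep_len=base.min_pep_len + d_len,
        )
        assert len(apply_filters(recs, stricter)) <= len(apply_filters(recs, base))


class TestConsensus:
    def _pair_records(self, make_record, reps_nseen):
        return [
            make_record(replicate_id=rep, nseen=n) for rep, n in reps_nseen.items()
        ]

    def test_mean_frequency_over_five_replicates(self, make_record):
        recs = self._pair_records(
            make_record, {f"rep{i}": n for i, n in enumerate([3, 4, 5, 2, 1], 1)}
        )
        links = build_consensus(recs, required_count=5, n_replicates=5)
        assert len(links) == 1
        assert links[0].mean_frequency == pytest.approx(3.0)
        assert links[0].n_replicates_present == 5

    def test_four_of_five_excluded(self, make_record):
        recs = self._pair_records(make_record, {f"rep{i}": 2 for i in range(1, 5)})
        assert build_consensus(recs, required_count=5, n_replicates=5) == []

    def test_required_one_gives_union(self, rng, make_record):
        recs = []
        pairs = set()
        for _ in range(30):
            a = int(rng.integers(244, 310))
            b = int(rng.integers(311, 381))
            pairs.add((a, b))
            recs.append(make_record(replicate_id=f"rep{rng.integers(1, 6)}", res_a=a, res_b=b))
        links = build_consensus(recs, required_count=1, n_replicates=5)
        assert {(l.res_a, l.res_b) for l in links} == pairs

    def test_antitone_in_required_count(self, rng, make_record):
        recs = []
        for _ in range(80):
            recs.append(
                make_record(
                    replicate_id=f"rep{rng.integers(1, 6)}",
                    res_a=int(rng.integers(244, 260)),
                    res_b=int(rng.integers(311, 330)),
                )
            )
        sizes = [len(build_consensus(recs, k, 5)) for k in range(1, 6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_brute_force_on_small_input(self, rng, make_record):
        recs = []
        for _ in range(50):
            recs.append(
                make_record(
                    replicate_id=f"rep{rng.integers(1, 6)}",
                    res_a=int(rng.integers(244, 255)),
                    res_b=int(rng.integers(311, 320)),
                    nseen=int(rng.integers(1, 9)),
                )
            )
        links = build_consensus(recs, required_count=3, n_replicates=5)
        # brute force: pair -> replicate -> max nseen
        table = {}
        for r in recs:
            table.setdefault((r.res_a, r.res_b), {}).setdefault(r.replicate_id, 0)
            table[(r.res_a, r.res_b)][r.replicate_id] = max(
                table[(r.res_a, r.res_b)][r.replicate_id], r.nseen
            )
        expected = {
            pair: np.mean(list(reps.values()))
            for pair, reps in table.items()
            if len(reps) >= 3
        }
        assert {(l.res_a, l.res_b): l.mean_frequency for l in links} == pytest.approx(expected)

    def test_duplicate_rows_in_one_replicate_count_once(self, make_record):
        recs = [
            make_record(replicate_id="rep1", nseen=2),
            make_record(replicate_id="rep1", nseen=7),
        ]
        links = build_consensus(recs, required_count=1, n_replicates=5)
        assert links[0].n_replicates_present == 1
        assert links[0].mean_frequency == pytest.approx(7.0)  # max row nseen

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no replicates"):
            build_consensus([], 5, 5)


class TestSectors:
    @pytest.mark.parametrize(
        "pair,sector,r2r3",
        [
            ((259, 290), "N-term", False),
            ((280, 321), "N-C", True),
            ((311, 375), "C-term", False),
            ((305, 306), "N-term", True),  # both sides of the repeat interface
            ((310, 311), "N-C", False),
        ],
    )
    def test_assignment(self, pair, sector, r2r3):
        assert assign_sector(*pair) == (sector, r2r3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match="out of range"):
            assign_sector(100, 321)

    def test_summary_conserves_total(self, rng):
        links = []
        for _ in range(40):
            a = int(rng.integers(244, 380))
            b = int(rng.integers(244, 380))
            if a == b:
                continue
            links.append(
                ConsensusLink(min(a, b), max(a, b), "WT", 37.0, 5, 2.0)
            )
        for s in summarize_sectors(links):
            assert s.n_term + s.c_term + s.n_c == s.total
            assert s.r2r3 <= s.total

    def test_three_sector_example(self):
        links = [
            ConsensusLink(259, 290, "WT", 37.0, 5, 1.0),
            ConsensusLink(280, 321, "WT", 37.0, 5, 1.0),
            ConsensusLink(311, 375, "WT", 37.0, 5, 1.0),
        ]
        (s,) = summarize_sectors(links)
        assert (s.n_term, s.n_c, s.c_term, s.r2r3, s.total) == (1, 1, 1, 1, 3)

    def test_empty_summary(self):
        assert summarize_sectors([]) == []


class TestDifferentialRetention:
    def _summary(self, cond, temp, n_term=0, c_term=0, n_c=0, r2r3=0):
        return xlms.SectorSummary(cond, temp, n_term, c_term, n_c, r2r3)

    def test_retained_fraction_vs_baseline(self):
        ref = [self._summary("WT", 37.0, n_term=20), self._summary("WT", 50.0, n_term=10)]
        alt = [self._summary("P301L", 37.0, n_term=20), self._summary("P301L", 50.0, n_term=5)]
        df = differential_retention(ref, alt)
        row = df[(df.sector == "N-term") & (df.temperature_c == 50.0)].iloc[0]
        assert row.ref_retained_fraction == pytest.approx(0.5)
        assert row.alt_retained_fraction == pytest.approx(0.25)
        assert row.alt_over_ref_ratio == pytest.approx(0.5)

    def test_identical_summaries_give_unit_ratio(self):
        ref = [self._summary("WT", 37.0, n_term=8, c_term=4)]
        df = differential_retention(ref, ref)
        assert (df[df.ref_count > 0].alt_over_ref_ratio == 1.0).all()

    def test_zero_alt_count_gives_zero_ratio(self):
        ref = [self._summary("WT", 37.0, n_term=8)]
        alt = [self._summary("P301L", 37.0, n_term=0)]
        df = differential_retention(ref, alt)
        assert df[df.sector == "N-term"].alt_over_ref_ratio.iloc[0] == 0.0

    def test_missing_baseline_errors(self):
        ref = [self._summary("WT", 50.0, n_term=8)]
        with pytest.raises(ValueError, match="baseline"):
            differential_retention(ref, ref)


class TestContactMatrix:
    def test_symmetric_single_link(self):
        mat = export_contact_matrix([ConsensusLink(280, 321, "WT", 37.0, 5, 3.0)])
        assert mat.loc[280, 321] == 3.0
        assert mat.loc[321, 280] == 3.0
        assert mat.to_numpy().sum() == 6.0

    def test_zero_matrix_and_trace(self):
        mat = export_contact_matrix([])
        assert (mat.to_numpy() == 0).all()
        assert np.trace(
            export_contact_matrix([ConsensusLink(280, 321, "WT", 37.0, 5, 3.0)]).to_numpy()
        ) == 0.0


class TestIO:
    def test_tsv_round_trip_with_decoy_column(self, tmp_path, make_record):
        path = tmp_path / "links.tsv"
        recs = [make_record(res_a=321, res_b=280), make_record(res_a=254, res_b=290)]
        xlms.write_crosslink_tsv(recs, path)
        # prepend a comment line and a decoy column is tolerated
        text = path.read_text()
        back = xlms.read_crosslink_tsv(path)
        assert len(back) == 2
        assert all(r.res_a <= r.res_b for r in back)  # canonicalized on read
        assert "# comment" not in text
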