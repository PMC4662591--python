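"""Z-scores, frequency tables, summaries, conversions, report files."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isomir.detect import (
    DetectionParams,
    ModificationCall,
    ModificationCatalog,
    ModificationType,
    detect_all,
)
from isomir.io import AlignedSet, MatureMiRNA, MiRNACatalog
from isomir.stats import (
    compute_scores,
    detect_conversions,
    frequency_table,
    read_details,
    summarize_library,
    write_reports,
)

from conftest import MIR548AV_SEQ, MIR548K_SEQ


def call(mirna, mtype, delta, read_seq, count, primary=True):
    return ModificationCall(mirna, mtype, delta, read_seq, count, primary)


def catalog_from_calls(calls, input_total=None, unmodified=None):
    cat = ModificationCatalog(calls=calls, unmodified=unmodified or {})
    for c in calls:
        if c.is_primary:
            cat.totals[c.mtype] += c.read_count
    cat.input_total_reads = input_total or (
        cat.total_modified_reads() + sum(cat.unmodified.values())
    )
    cat.considered_reads = cat.input_total_reads
    return cat


def synthetic_score_catalog(layout):
    """Build a catalog whose miRNA i has n_i distinct events of r_i reads.

    layout: list of (n_events, reads_per_event); s_i = n_i * (n_i * r_i).
    """
    calls = []
    for i, (n_events, per_event) in enumerate(layout):
        for e in range(n_events):
            calls.append(
                call(f"mir-{i:03d}", ModificationType.ADD3, "A",
                     f"READ{i}E{e}", per_event)
            )
    return catalog_from_calls(calls)


class TestComputeScores:
    def test_hand_computed_population_z(self):
        # s = {2, 4, 12}: mu = 6, population sigma = sqrt(56/3)
        cat = synthetic_score_catalog([(1, 2), (1, 4), (2, 3)])
        ss = compute_scores(cat)
        s_vals = {p.mirna_id: p.s for p in ss}
        assert s_vals == {"mir-000": 2.0, "mir-001": 4.0, "mir-002": 12.0}
        assert ss.mu == pytest.approx(6.0)
        assert ss.sigma == pytest.approx(math.sqrt(56 / 3))
        z = {p.mirna_id: p.z for p in ss}
        assert z["mir-002"] == pytest.approx((12 - 6) / math.sqrt(56 / 3), abs=1e-9)
        assert z["mir-002"] == pytest.approx(1.38873015, abs=1e-6)

    def test_degenerate_sigma_yields_zero_z_with_warning(self, caplog):
        cat = synthetic_score_catalog([(1, 5)])
        with caplog.at_level("WARNING", logger="isomir.stats"):
            ss = compute_scores(cat)
        assert [p.z for p in ss] == [0.0]
        assert "Z-scores set to 0" in caplog.text

    def test_score_at_mean_has_zero_z(self):
        cat = synthetic_score_catalog([(1, 2), (1, 4), (1, 6)])
        ss = compute_scores(cat)
        assert next(p.z for p in ss if p.s == 4.0) == pytest.approx(0.0, abs=1e-12)

    @given(
        st.lists(
            st.tuples(st.integers(1, 4), st.integers(1, 50)),
            min_size=2,
            max_size=30,
        )
    )
    @settings(derandomize=True, max_examples=100)
    def test_standardization_invariants(self, layout):
        """mean(z) = 0 and population SD(z) = 1 whenever sigma > 0."""
        cat = synthetic_score_catalog(layout)
        ss = compute_scores(cat)
        s = np.array([p.s for p in ss])
        z = np.array([p.z for p in ss])
        expected = (s - s.mean()) / s.std() if s.std() > 0 else np.zeros_like(s)
        np.testing.assert_allclose(z, expected, atol=1e-9)
        if s.std() > 0:
            assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9

    def test_empty_catalog_gives_empty_scores(self):
        assert len(compute_scores(ModificationCatalog())) == 0


class TestFrequencyTable:
    def test_single_pattern_is_100_percent(self):
        cat = catalog_from_calls([call("m", ModificationType.ADD3, "A", "R1", 7)])
        t = frequency_table(cat, ModificationType.ADD3)
        assert t.rows == {"A": 100.0}

    def test_three_to_one_split(self):
        cat = catalog_from_calls(
            [
                call("m", ModificationType.ADD3, "A", "R1", 30),
                call("m2", ModificationType.ADD3, "T", "R2", 10),
            ]
        )
        t = frequency_table(cat, ModificationType.ADD3)
        assert t.rows == {"A": 75.0, "T": 25.0}

    def test_by_unique_ignores_abundance(self):
        cat = catalog_from_calls(
            [
                call("m", ModificationType.ADD3, "A", "R1", 999),
                call("m2", ModificationType.ADD3, "T", "R2", 1),
            ]
        )
        t = frequency_table(cat, ModificationType.ADD3, by_unique=True)
        assert t.rows == {"A": 50.0, "T": 50.0}

    def test_others_bucket_and_total(self):
        cat = catalog_from_calls(
            [
                call("m", ModificationType.ADD3, "A", "R1", 97),
                call("m2", ModificationType.ADD3, "GG", "R2", 2),
                call("m3", ModificationType.ADD3, "C", "R3", 1),
            ]
        )
        t = frequency_table(cat, ModificationType.ADD3, other_threshold=1.5)
        assert set(t.rows) == {"A", "GG"}
        assert t.other_bucket == pytest.approx(1.0)
        assert t.total() == pytest.approx(100.0, abs=1e-9)

    def test_no_calls_of_type_is_empty_not_error(self):
        cat = catalog_from_calls([call("m", ModificationType.ADD3, "A", "R1", 5)])
        assert not frequency_table(cat, ModificationType.TRIM5)

    def test_only_primary_calls_counted(self):
        cat = catalog_from_calls(
            [
                call("m", ModificationType.ADD3, "A", "R1", 10, primary=True),
                call("m2", ModificationType.ADD3, "T", "R1", 10, primary=False),
            ]
        )
        assert frequency_table(cat, ModificationType.ADD3).rows == {"A": 100.0}


class TestSummarizeLibrary:
    def test_no_modifications(self):
        cat = catalog_from_calls([], input_total=100, unmodified={"m": 100})
        s = summarize_library(cat)
        assert s.percent_modified_reads == 0.0 and s.top_mirna is None

    def test_forty_percent_modified_by_construction(self):
        cat = catalog_from_calls(
            [call("mir-a", ModificationType.TRIM3, "G", "R1", 40)],
            input_total=100,
            unmodified={"mir-b": 60},
        )
        assert summarize_library(cat).percent_modified_reads == pytest.approx(40.0)

    def test_top_mirna_and_tie_break(self):
        cat = catalog_from_calls(
            [
                call("mir-b", ModificationType.ADD3, "A", "R1", 50),
                call("mir-a", ModificationType.ADD3, "T", "R2", 50),
                call("mir-c", ModificationType.ADD3, "C", "R3", 10),
            ]
        )
        assert summarize_library(cat).top_mirna == ("mir-a", 50)

    def test_length_histogram_by_type(self):
        cat = catalog_from_calls(
            [
                call("m", ModificationType.ADD3, "A", "R1", 90),
                call("m", ModificationType.ADD3, "AT", "R2", 10),
                call("m", ModificationType.TRIM5, "GGG", "R3", 5),
            ]
        )
        h = summarize_library(cat).length_histogram
        assert h[ModificationType.ADD3] == {1: 90, 2: 10}
        assert h[ModificationType.TRIM5] == {3: 5}

    def test_totals_agree_with_detection(self, default_simulation):
        _, _, catalog, reads, aligned, _ = default_simulation
        res = detect_all(reads, catalog, aligned)
        assert summarize_library(res).totals == res.totals

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            summarize_library(ModificationCatalog())


class TestConversions:
    def test_worked_example_3p_tcgt(self, worked_example_catalog):
        events = detect_conversions(worked_example_catalog)
        hits = [e for e in events if e.source_id == "hsa-miR-548k"]
        assert len(hits) == 1
        e = hits[0]
        assert e.product_id == "hsa-miR-548av-5p"
        assert e.trimmed_end == "3p" and e.trimmed_seq == "TCGT"
        assert MIR548K_SEQ[: -len(e.trimmed_seq)] == MIR548AV_SEQ

    def test_no_containment_no_events(self):
        cat = MiRNACatalog(
            [MatureMiRNA("a", "ACCGGTTACCGGTTACCGGT"), MatureMiRNA("b", "TGGCCAATGGCCAATGGCCA")]
        )
        assert detect_conversions(cat) == []

    def test_synthetic_3p_pair(self):
        cat = MiRNACatalog(
            [
                MatureMiRNA("X", "ACGTACGTACGTACGTACGT"),
                MatureMiRNA("Y", "ACGTACGTACGTACGTAC"),
            ]
        )
        events = detect_conversions(cat)
        assert [(e.source_id, e.product_id, e.trimmed_end, e.trimmed_seq) for e in events] == [
            ("X", "Y", "3p", "GT")
        ]

    def test_catalog_mode_agrees_with_brute_force(self):
        """Catalog-only scan = O(n^2 * max_delta) brute-force containment."""
        import random

        rng = random.Random(11)
        seqs = set()
        while len(seqs) < 60:
            seqs.add("".join(rng.choices("ACGT", k=rng.randint(8, 14))))
        seqs = sorted(seqs)
        # plant guaranteed containments
        seqs += [seqs[0] + "TT", "CAG" + seqs[1]]
        cat = MiRNACatalog([MatureMiRNA(f"m-{i:02d}", s) for i, s in enumerate(seqs)])
        expected = set()
        for x in cat:
            for y in cat:
                if x.id == y.id or x.seq == y.seq:
                    continue
                for d in range(1, 6):
                    if len(x.seq) - len(y.seq) == d:
                        if x.seq[: len(y.seq)] == y.seq:
                            expected.add((x.id, y.id, "3p", x.seq[len(y.seq):]))
                        if x.seq[d:] == y.seq:
                            expected.add((x.id, y.id, "5p", x.seq[:d]))
        got = {(e.source_id, e.product_id, e.trimmed_end, e.trimmed_seq)
               for e in detect_conversions(cat)}
        assert got == expected and len(got) >= 2

    def test_calls_mode_reports_observed_conversions(self, worked_example_catalog):
        calls = [
            call("hsa-miR-548k", ModificationType.TRIM3, "TCGT", MIR548AV_SEQ, 12),
            call("hsa-miR-9-5p", ModificationType.TRIM5, "T",
                 "CTTTGGTTATCTAGCTGTATGA", 5),
        ]
        events = detect_conversions(worked_example_catalog, calls=calls)
        assert [(e.source_id, e.product_id) for e in events] == [
            ("hsa-miR-548k", "hsa-miR-548av-5p")
        ]


class TestWriteReports:
    def _full_outputs(self, cat):
        summary = summarize_library(cat)
        scores = compute_scores(cat)
        tables = {t: frequency_table(cat, t) for t in ModificationType}
        return summary, scores, tables

    def test_details_round_trip(self, tmp_path):
        cat = catalog_from_calls(
            [
                call("mir-a", ModificationType.ADD3, "A", "ACGTACGTACGTACGTACA", 30),
                call("mir-b", ModificationType.TRIM5, "TG", "GTACGTACGTACGTAC", 12),
                call("mir-c", ModificationType.ADD5, "C", "CACGTACGTACGTACGT", 10,
                     primary=False),
            ]
        )
        summary, scores, tables = self._full_outputs(cat)
        write_reports(cat, summary, scores, tables, [], tmp_path)
        back = read_details(tmp_path / "details.tsv")
        assert back == cat.calls

    def test_empty_catalog_writes_headers_only(self, tmp_path):
        cat = catalog_from_calls([], input_total=10, unmodified={"m": 10})
        summary, scores, tables = self._full_outputs(cat)
        paths = write_reports(cat, summary, scores, tables, [], tmp_path)
        for p in paths:
            text = open(p).read()
            assert text.strip()  # headers present
        assert open(tmp_path / "details.tsv").read().count("\n") == 1

    def test_frequency_rows_in_descending_percent(self, tmp_path):
        cat = catalog_from_calls(
            [
                call("m1", ModificationType.ADD3, "T", "R1", 10),
                call("m2", ModificationType.ADD3, "A", "R2", 80),
                call("m3", ModificationType.ADD3, "G", "R3", 10),
            ]
        )
        summary, scores, tables = self._full_outputs(cat)
        write_reports(cat, summary, scores, tables, [], tmp_path)
        lines = open(tmp_path / "frequency_add3.tsv").read().splitlines()[1:]
        percents = [float(l.split("\t")[1]) for l in lines]
        assert percents == sorted(percents, reverse=True)
        assert lines[0].startswith("A\t")
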