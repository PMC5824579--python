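"""Entry categorization, B_max verdicts, trimming, corpus filters."""

import itertools

import numpy as np
import pytest

from bmaxcheck import (
    FilterRules,
    MissingReport,
    SynthSpec,
    categorize_entry,
    corpus_fraction_over_bmax,
    filter_corpus,
    gen_structure,
    parse_pdb,
    shipped_table,
    trim_to_bmax,
    validate_entry,
)
from bmaxcheck.errors import BmaxError, ResolutionOutOfRangeError, UntrimmableError

from conftest import make_atom, model_from_bs


def synthetic_model(b_mean, resolution, seed=0, b_sd=0.0, **kwargs):
    spec = SynthSpec(n_residues=30, b_mean=b_mean, b_sd=b_sd,
                     resolution=resolution, seed=seed, **kwargs)
    text, _ = gen_structure(spec)
    return parse_pdb(text, entry_id=f"M{seed}")


class TestCategorize:
    def test_clean_entry(self):
        m = model_from_bs([20, 50, 99.9])
        assert categorize_entry(m).name == "clean"

    def test_large_b_and_missing(self):
        m = model_from_bs([20, 100.01])
        m.missing = MissingReport(missing_residues=[("A", 5, "GLY")])
        assert categorize_entry(m).name == "large_b_and_missing"

    def test_threshold_is_strictly_greater_than_100(self):
        assert not categorize_entry(model_from_bs([100.00])).has_large_b
        assert categorize_entry(model_from_bs([100.01])).has_large_b

    def test_four_categories_partition_a_corpus(self):
        corpus = []
        for large, missing in itertools.product([False, True], repeat=2):
            m = model_from_bs([120.0 if large else 30.0])
            if missing:
                m.missing = MissingReport(zero_occ_atoms=[("A", 1, "ALA", "CB")])
            corpus.append(m)
        names = [categorize_entry(m).name for m in corpus]
        assert sorted(names) == sorted(
            ["clean", "missing_only", "large_b_only", "large_b_and_missing"]
        )


class TestValidateEntry:
    def test_low_mean_b_at_high_resolution_passes(self):
        rep = validate_entry(synthetic_model(24.0, 1.4), shipped_table())
        assert rep.verdict == "pass" and rep.b_max == 25.0

    def test_above_bmax_but_inside_ci_band(self):
        """Mean 90 at 3.1 Å: bin 7 reference is 83(9), so 90 is above B_max
        but not above B_max + CI = 92."""
        rep = validate_entry(synthetic_model(90.0, 3.1), shipped_table())
        assert rep.verdict == "above_bmax"
        assert (rep.b_max, rep.ci) == (83.0, 9.0)

    def test_far_above_bmax(self):
        rep = validate_entry(synthetic_model(45.0, 1.2), shipped_table())
        assert rep.verdict == "above_bmax_plus_ci"

    def test_mean_exactly_at_bmax_passes(self):
        rep = validate_entry(synthetic_model(43.0, 1.9), shipped_table())
        assert rep.mean_b == pytest.approx(43.0, abs=1e-9)
        assert rep.verdict == "pass"

    def test_missing_resolution_is_unvalidatable(self):
        m = synthetic_model(30.0, 2.0)
        m.resolution = None
        with pytest.raises(ResolutionOutOfRangeError):
            validate_entry(m, shipped_table())
        # a sidecar resolution rescues it
        rep = validate_entry(m, shipped_table(), resolution=2.0)
        assert rep.bin_index == 3

    def test_trim_flag_reports_removed_atoms(self):
        # wide B spread: mean exceeds B_max but many atoms sit well below it
        m = synthetic_model(30.0, 1.2, seed=6, b_sd=10.0)
        rep = validate_entry(m, shipped_table(), trim=True)
        assert rep.verdict != "pass"
        assert len(rep.trimmed_atoms) > 0


class TestTrim:
    def test_nothing_removed_when_already_under(self):
        kept, removed = trim_to_bmax(model_from_bs([10, 20, 30]), b_max=25.0)
        assert removed == [] and len(kept) == 3

    def test_single_outlier_removed(self):
        m = model_from_bs([10, 20, 90])
        kept, removed = trim_to_bmax(m, b_max=20.0)
        assert [a.b_factor for a in removed] == [90]
        assert np.mean([a.b_factor for a in kept]) <= 20.0

    def test_untrimmable_when_every_atom_exceeds(self):
        with pytest.raises(UntrimmableError):
            trim_to_bmax(model_from_bs([50, 60]), b_max=40.0)

    def test_kept_mean_never_above_threshold(self, rng):
        for _ in range(20):
            bs = list(rng.uniform(5, 150, size=15))
            m = model_from_bs(bs)
            try:
                kept, removed = trim_to_bmax(m, b_max=40.0)
            except UntrimmableError:
                assert min(bs) > 40.0
                continue
            protein_kept = [a.b_factor for a in kept if a.is_protein]
            assert np.mean(protein_kept) <= 40.0 + 1e-12
            assert len(protein_kept) + len(removed) == 15

    def test_greedy_matches_exhaustive_minimum(self, rng):
        """On instances small enough to enumerate, the removed-set size is
        the minimum over all subsets achieving mean <= b_max."""
        for trial in range(25):
            n = int(rng.integers(2, 13))
            bs = [round(float(b), 2) for b in rng.uniform(5, 140, size=n)]
            b_max = float(rng.uniform(20, 80))
            m = model_from_bs(bs)
            try:
                _, removed = trim_to_bmax(m, b_max=b_max)
                greedy_k = len(removed)
            except UntrimmableError:
                greedy_k = None
            best = None
            for k in range(n):
                for keep in itertools.combinations(range(n), n - k):
                    if np.mean([bs[i] for i in keep]) <= b_max:
                        best = k
                        break
                if best is not None:
                    break
            assert greedy_k == best


class TestFilterCorpus:
    def good(self, **overrides):
        m = model_from_bs([30.0], r_factor=0.2, free_r=0.25, temperature=100.0,
                          deposition_year=2005)
        for key, val in overrides.items():
            setattr(m, key, val)
        return m

    def test_well_behaved_entry_kept(self):
        kept, rejected = filter_corpus([self.good()])
        assert len(kept) == 1 and not rejected

    @pytest.mark.parametrize(
        "override,reason_word",
        [
            ({"temperature": 293.0}, "temperature"),
            ({"temperature": 94.0}, "temperature"),
            ({"free_r": 0.31}, "R"),
            ({"r_factor": 0.35}, "R"),
        ],
    )
    def test_default_rules_reject(self, override, reason_word):
        _, rejected = filter_corpus([self.good(**override)])
        assert len(rejected) == 1
        assert reason_word.lower() in rejected[0][1].lower()

    def test_nucleic_acid_entries_rejected(self):
        m = self.good()
        m.atoms.append(make_atom(serial=9, atom_name="P", res_name="DA",
                                 res_seq=50, element="P"))
        _, rejected = filter_corpus([m])
        assert "nucleic" in rejected[0][1]

    def test_both_exceed_reading_is_configurable(self):
        m = self.good(free_r=0.31)
        kept, _ = filter_corpus([m], FilterRules(r_either=False))
        assert kept == [m]

    def test_year_cutoff(self):
        old, new = self.good(), self.good(deposition_year=2014)
        kept, rejected = filter_corpus([old, new], FilterRules(max_year=2008))
        assert kept == [old] and rejected[0][0] is new

    def test_missing_metadata_rejected_with_reason(self):
        m = self.good(temperature=None)
        _, rejected = filter_corpus([m])
        assert rejected[0][1] == "missing metadata"

    def test_filtering_is_idempotent(self):
        corpus = [self.good(), self.good(temperature=200.0), self.good(free_r=0.4)]
        kept, _ = filter_corpus(corpus)
        again, rejected = filter_corpus(kept)
        assert again == kept and not rejected


class TestCorpusFraction:
    def _report(self, bin_index, verdict):
        from bmaxcheck import ValidationReport, EntryCategory
        return ValidationReport(
            entry_id="x", resolution=2.0, bin_index=bin_index, pcvol=50.0,
            mean_b=30.0, b_max=43.0, ci=2.0, verdict=verdict,
            category=EntryCategory(False, False),
        )

    def test_all_pass_is_zero_everywhere(self):
        reports = [self._report(1, "pass")] * 4 + [self._report(5, "pass")] * 2
        assert corpus_fraction_over_bmax(reports) == {1: 0.0, 5: 0.0}

    def test_constructed_thirty_percent(self):
        reports = [self._report(1, "above_bmax")] * 3 + [self._report(1, "pass")] * 7
        assert corpus_fraction_over_bmax(reports) == {1: 30.0}

    def test_empty_bins_absent_not_zero(self):
        reports = [self._report(2, "above_bmax_plus_ci")]
        out = corpus_fraction_over_bmax(reports)
        assert out == {2: 100.0}
        assert 1 not in out
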