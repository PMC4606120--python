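"""Window log-odds scoring, PrD calling, and region summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prdkit import (
    CompositionModel,
    ProteinRecord,
    ProteomeSet,
    ScoringParams,
    composition_summary,
    default_background_model,
    default_prion_model,
    prd_localization,
    scan_protein,
    scan_proteome,
    window_score,
)
from prdkit.annotation import DomainArchitecture
from prdkit.synthetic_data import (
    SyntheticProteomeParams,
    generate_proteome,
    score_calls_against_truth,
)

WINDOWS = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80)


class TestCompositionModel:
    def test_probabilities_sum_to_one(self):
        model = CompositionModel({"N": 3, "Q": 1})
        assert math.isclose(sum(model.probs.values()), 1.0, abs_tol=1e-9)
        assert all(p > 0 for p in model.probs.values())

    def test_pseudocount_keeps_absent_residues_positive(self):
        model = CompositionModel({"N": 1.0})
        assert model.probs["W"] > 0

    def test_default_models_load_and_normalize(self):
        for model in (default_prion_model(), default_background_model()):
            assert math.isclose(sum(model.probs.values()), 1.0, abs_tol=1e-9)
        prion = default_prion_model()
        # paper-reported region composition, up to the pseudocount
        assert prion.probs["N"] == pytest.approx(0.30, abs=1e-3)
        assert prion.probs["Q"] == pytest.approx(0.21, abs=1e-3)

    def test_tsv_roundtrip(self, tmp_path):
        model = CompositionModel({"N": 0.5, "Q": 0.5})
        path = tmp_path / "m.tsv"
        model.to_tsv(path)
        # reload with a negligible pseudocount: the file already carries it
        back = CompositionModel.from_tsv(path, pseudocount=1e-15)
        for a in "NQAW":
            assert back.probs[a] == pytest.approx(model.probs[a], rel=1e-6)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            CompositionModel({"J": 1.0})
        with pytest.raises(ValueError):
            CompositionModel({"N": -1.0})
        with pytest.raises(ValueError):
            CompositionModel({"N": 1.0}, pseudocount=0)


class TestWindowScore:
    def test_hand_computed_value(self, nq_model, nq_background):
        # 4 residues, each log2(0.25/0.05) = log2(5)
        assert window_score("NNQQ", nq_model, nq_background) == pytest.approx(
            4 * math.log2(5), abs=1e-6
        )

    def test_ambiguity_codes_contribute_zero(self, nq_model, nq_background):
        base = window_score("A", nq_model, nq_background)
        assert window_score("AB", nq_model, nq_background) == pytest.approx(base)
        assert window_score("XZUO", nq_model, nq_background) == pytest.approx(0.0)

    def test_empty_window_rejected(self, flat_model):
        with pytest.raises(ValueError):
            window_score("", flat_model, flat_model)

    @given(WINDOWS)
    def test_zero_under_identical_models(self, window):
        model = default_prion_model()
        assert window_score(window, model, model) == pytest.approx(0.0, abs=1e-9)

    @given(WINDOWS, WINDOWS)
    def test_score_additivity(self, x, y):
        prion, bg = default_prion_model(), default_background_model()
        assert window_score(x + y, prion, bg) == pytest.approx(
            window_score(x, prion, bg) + window_score(y, prion, bg), abs=1e-9
        )

    @given(WINDOWS)
    def test_permutation_invariance(self, window):
        prion, bg = default_prion_model(), default_background_model()
        assert window_score(window[::-1], prion, bg) == pytest.approx(
            window_score(window, prion, bg), abs=1e-9
        )

    def test_monotone_in_likelihood_ratio(self):
        """Swapping a residue for one with a higher prion/background ratio
        strictly increases the score."""
        prion, bg = default_prion_model(), default_background_model()
        ratio = {a: prion.probs[a] / bg.probs[a] for a in prion.probs}
        assert ratio["N"] > ratio["L"]
        low = window_score("LAAA", prion, bg)
        high = window_score("NAAA", prion, bg)
        assert high > low


class TestScanProtein:
    def _models(self):
        return default_prion_model(), default_background_model()

    def test_background_protein_not_called(self):
        prion, bg = self._models()
        rec = ProteinRecord("p1", "ACDEFGHIKLMNPQRSTVWY" * 10)
        call, secondary = scan_protein(rec, prion, bg)
        assert call is None and secondary == []

    def test_pure_prion_window_called_with_coordinates(self):
        prion, bg = self._models()
        flank = "ALKEIV" * 20  # 120 background-ish residues
        core = "NNNQQS" * 15   # 90 strongly biased residues
        rec = ProteinRecord("p1", flank + core + flank)
        call, _ = scan_protein(rec, prion, bg)
        assert call is not None
        assert call.score_bits >= 50
        assert call.length >= 60
        # called region concentrates on the planted core
        overlap = min(call.end, 210) - max(call.start, 121) + 1
        assert overlap >= 45
        assert call.region_sequence == rec.sequence[call.start - 1 : call.end]

    def test_short_protein_scanned_as_single_window(self):
        prion, bg = self._models()
        rec = ProteinRecord("p1", "N" * 30)
        call, _ = scan_protein(rec, prion, bg,
                               ScoringParams(cutoff_bits=20.0))
        assert call is not None
        assert (call.start, call.end) == (1, 30)

    def test_cutoff_is_inclusive_after_rounding_by_default(self, flat_model):
        biased = CompositionModel({"N": 2.0, **{a: 1.0 for a in "ACDE"}},
                                  pseudocount=1e-12)
        rec = ProteinRecord("p1", "N" * 10)
        probe, _ = scan_protein(rec, biased, flat_model,
                                ScoringParams(window_length=10,
                                              cutoff_bits=0.0))
        tie = probe.score_bits  # exact rounded score of the only window
        params = ScoringParams(window_length=10, cutoff_bits=tie)
        call, _ = scan_protein(rec, biased, flat_model, params)
        assert call is not None
        strict = ScoringParams(window_length=10, cutoff_bits=tie,
                               strict_greater=True)
        call, _ = scan_protein(rec, biased, flat_model, strict)
        assert call is None

    def test_two_separated_regions_yield_one_call_plus_secondary(self):
        prion, bg = self._models()
        core = "NNQNQS" * 12  # 72 biased residues
        gap = "ALKEIV" * 30   # 180 background residues
        rec = ProteinRecord("p1", core + gap + core + "NNNNNN")
        call, secondary = scan_protein(rec, prion, bg)
        assert call is not None
        assert len(secondary) == 1
        s_start, s_end, s_score = secondary[0]
        assert s_score >= 50
        # secondary region does not overlap the primary call
        assert s_end < call.start or s_start > call.end

    def test_deterministic_across_runs(self):
        prion, bg = self._models()
        rec = ProteinRecord("p1", "NQS" * 50)
        first = scan_protein(rec, prion, bg)
        second = scan_protein(rec, prion, bg)
        assert first == second

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ScoringParams(window_length=0)
        with pytest.raises(ValueError):
            ScoringParams(step=0)
        with pytest.raises(ValueError):
            ScoringParams(cutoff_bits=float("inf"))


class TestPlantedRecovery:
    def test_planted_80mer_recovered_in_95pct_of_replicates(self):
        """A planted 80-residue PrD-composition segment inside 200
        background residues is recovered (>= 50% overlap) in >= 95% of 200
        seeded replicates."""
        prion, bg = default_prion_model(), default_background_model()
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            params = SyntheticProteomeParams(
                n_proteins=1, length_min=200, length_max=200,
                prd_fraction=1.0, prd_length_min=80, prd_length_max=80,
                seed=seed,
            )
            proteome, truth = generate_proteome(params)
            rec = proteome.records[0]
            t_start, t_end = truth.prd_intervals[rec.accession]
            call, _ = scan_protein(rec, prion, bg)
            if call is None:
                continue
            overlap = min(call.end, t_end) - max(call.start, t_start) + 1
            if overlap >= 0.5 * (t_end - t_start + 1):
                hits += 1
        assert hits >= 0.95 * n_rep


class TestScanProteome:
    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            scan_proteome(ProteomeSet([]))

    def test_no_planted_gives_zero_fraction(self):
        params = SyntheticProteomeParams(n_proteins=50, prd_fraction=0.0,
                                         seed=3)
        proteome, _ = generate_proteome(params)
        calls = scan_proteome(proteome)
        assert calls.fraction_positive == 0.0

    def test_per_organism_counts_sum_to_total(self):
        params_a = SyntheticProteomeParams(n_proteins=100, prd_fraction=0.2,
                                           organism="orgA", seed=5)
        params_b = SyntheticProteomeParams(
            n_proteins=100, prd_fraction=0.2, organism="orgB",
            accession_prefix="SYNB", seed=6,
        )
        prot_a, _ = generate_proteome(params_a)
        prot_b, _ = generate_proteome(params_b)
        merged = ProteomeSet(prot_a.records + prot_b.records)
        calls = scan_proteome(merged)
        assert sum(calls.per_organism_counts().values()) == calls.n_calls
        assert calls.n_calls > 0

    def test_calls_land_on_planted_proteins(self):
        params = SyntheticProteomeParams(n_proteins=2000, prd_fraction=0.01,
                                         seed=11)
        proteome, truth = generate_proteome(params)
        calls = scan_proteome(proteome)
        stats = score_calls_against_truth(calls, truth)
        assert stats.fp <= 1
        assert stats.sensitivity >= 0.8


class TestCompositionSummary:
    def test_single_region(self, call_factory):
        call = call_factory("p1", 1, 4, seq="NQ")
        call.region_sequence = "NNQQ"
        freqs = composition_summary([call])
        assert freqs["N"] == 0.5 and freqs["Q"] == 0.5
        assert freqs.drop(["N", "Q"]).eq(0).all()

    def test_frequencies_sum_to_one(self, call_factory):
        call = call_factory("p1", 1, 7)
        call.region_sequence = "NQSGALK"
        assert composition_summary([call]).sum() == pytest.approx(1.0, abs=1e-9)

    def test_ambiguity_codes_excluded(self, call_factory):
        call = call_factory("p1", 1, 4)
        call.region_sequence = "NNXB"
        freqs = composition_summary([call])
        assert freqs["N"] == 1.0

    def test_empty_call_set_rejected(self):
        with pytest.raises(ValueError):
            composition_summary([])


class TestLocalization:
    @pytest.mark.parametrize(
        "call_span,domains,expected",
        [
            ((5, 70), [("PF1", 100, 200)], "N-terminal"),
            ((210, 280), [("PF1", 100, 200), ("PF2", 300, 400)],
             "inter-domain"),
            ((250, 320), [("PF1", 100, 200)], "C-terminal"),
            ((150, 220), [("PF1", 100, 200)], "overlapping"),
            ((5, 70), [], "undomained"),
        ],
    )
    def test_labels(self, call_factory, call_span, domains, expected):
        call = call_factory("p1", *call_span)
        arch = DomainArchitecture(accession="p1", domains=domains)
        assert prd_localization(call, arch) == expected

    def test_small_touch_is_not_overlap(self, call_factory):
        # 5 residues of overlap on a 100-residue call is 5% <= 10%
        call = call_factory("p1", 1, 100)
        arch = DomainArchitecture(accession="p1", domains=[("PF1", 96, 200)])
        assert prd_localization(call, arch) == "N-terminal"

    def test_accession_mismatch_rejected(self, call_factory):
        call = call_factory("p1", 1, 60)
        arch = DomainArchitecture(accession="p2", domains=[])
        with pytest.raises(ValueError):
            prd_localization(call, arch)
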