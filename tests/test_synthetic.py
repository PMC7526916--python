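"""Synthetic cohort generator: structure, determinism and injected effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brcalike.errors import InvalidConfigError, InvalidInputError
from brcalike.signatures import CHANNELS, fit_cohort_weights
from brcalike.synthetic import (
    CohortConfig,
    GroupSpec,
    generate_cohort,
    generate_signature_matrix,
    generate_spectra,
)


class TestSignatureMatrix:
    def test_rows_are_stochastic_and_distinct(self):
        S = generate_signature_matrix(27, seed=7)
        assert S.shape == (27, 96)
        assert np.all(S >= 0)
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-12)
        normed = S / np.linalg.norm(S, axis=1, keepdims=True)
        cos = normed @ normed.T
        np.fill_diagonal(cos, 0.0)
        assert cos.max() < 0.99

    def test_seed_determinism(self):
        np.testing.assert_array_equal(
            generate_signature_matrix(2, seed=1), generate_signature_matrix(2, seed=1)
        )

    def test_k_below_two_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_signature_matrix(1)


class TestGenerateSpectra:
    def test_channel_totals_equal_mutation_count(self, small_signatures, rng):
        W = rng.dirichlet(np.ones(5), size=8)
        spectra = generate_spectra(W, small_signatures, 137, seed=2)
        assert np.all(spectra.sum(axis=1) == 137)

    def test_pure_signature_frequencies_converge(self, small_signatures):
        w = np.zeros(5)
        w[3] = 1.0
        spec = generate_spectra(w, small_signatures, 10**6, seed=9)[0]
        freqs = spec / spec.sum()
        assert np.abs(freqs - small_signatures[3]).max() < 0.002

    def test_zero_mutations_rejected(self, small_signatures):
        with pytest.raises(InvalidInputError):
            generate_spectra(np.full(5, 0.2), small_signatures, 0, seed=1)

    def test_negative_weight_rejected(self, small_signatures):
        w = np.array([1.2, -0.2, 0.0, 0.0, 0.0])
        with pytest.raises(InvalidInputError):
            generate_spectra(w, small_signatures, 10, seed=1)


class TestGenerateCohort:
    def test_seed_determinism_byte_identical(self):
        cfg = CohortConfig(
            n_patients=40,
            n_signatures=4,
            n_genes_expression=10,
            group_specs=(GroupSpec("BRCA1", "hypermethylation", 4, 0.5, 0),),
            seed=5,
        )
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for name in ("aberrations", "spectra", "expression", "methylation_probes", "clinical"):
            assert getattr(a, name).to_csv() == getattr(b, name).to_csv()

    def test_oversized_groups_rejected(self):
        cfg = CohortConfig(
            n_patients=10,
            group_specs=(GroupSpec("BRCA1", "germline_mutation", 11, 0.5, 0),),
        )
        with pytest.raises(InvalidConfigError):
            generate_cohort(cfg)

    def test_delta_outside_unit_interval_rejected(self):
        cfg = CohortConfig(
            n_patients=10,
            group_specs=(GroupSpec("BRCA1", "germline_mutation", 2, 1.5, 0),),
        )
        with pytest.raises(InvalidConfigError):
            generate_cohort(cfg)

    def test_patient_roster_covers_all_tables(self, small_cohort):
        roster = set(small_cohort.patients)
        assert set(small_cohort.spectra.index) <= roster
        assert set(small_cohort.expression.columns) <= roster
        assert set(small_cohort.aberrations.patient_id) <= roster
        assert set(small_cohort.clinical.index) <= roster

    def test_ground_truth_covers_injected_events(self, small_cohort):
        gt = small_cohort.ground_truth
        hyper_members = set(gt.group_members["BRCA2:hypermethylation"])
        assert {p for (p, g) in gt.hypermethylation if g == "BRCA2"} == hyper_members
        assert all(g in set(small_cohort.expression.index) for (_, g) in gt.low_expression)

    def test_spectra_columns_are_canonical_channels(self, small_cohort):
        assert list(small_cohort.spectra.columns) == list(CHANNELS)

    def test_enriched_group_has_elevated_fitted_hrd_weight(self, small_cohort):
        weights, _ = fit_cohort_weights(small_cohort.spectra, small_cohort.signatures)
        hrd_col = weights.columns[small_cohort.ground_truth.hrd_index]
        members = small_cohort.ground_truth.group_members["BARD1:somatic_mutation"]
        background = [
            p for p in small_cohort.patients
            if all(p not in m for m in small_cohort.ground_truth.group_members.values())
        ]
        assert weights.loc[members, hrd_col].mean() > weights.loc[background, hrd_col].mean()

    def test_null_group_weights_exchangeable_with_background(self):
        # with delta = 0 the designated group's true HRD weights match the
        # background distribution (KS test at n = 200)
        cfg = CohortConfig(
            n_patients=400,
            n_signatures=6,
            n_genes_expression=10,
            group_specs=(GroupSpec("ATM", "somatic_mutation", 200, 0.0, 0),),
            seed=23,
        )
        cohort = generate_cohort(cfg)
        hrd = cohort.ground_truth.true_weights.iloc[:, 0]
        members = cohort.ground_truth.group_members["ATM:somatic_mutation"]
        rest = [p for p in cohort.patients if p not in set(members)]
        ks = stats.ks_2samp(hrd[members], hrd[rest])
        assert ks.pvalue > 0.01

    def test_write_round_trip(self, small_cohort, tmp_path):
        paths = small_cohort.write(tmp_path)
        assert set(paths) == {
            "aberrations.tsv",
            "spectra.tsv",
            "signatures.tsv",
            "expression.tsv",
            "methylation_probes.tsv",
            "clinical.tsv",
            "ground_truth.tsv",
        }
        spectra = pd.read_csv(paths["spectra.tsv"], sep="\t", index_col=0)
        assert spectra.shape == small_cohort.spectra.shape
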