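"""Ground-truth generator, platform emulators and their determinism."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import pausetrack as pt
from pausetrack.errors import ValidationError
from pausetrack.simulate import read_truth, write_truth


class TestTransitionMatrix:
    def test_rows_are_stochastic(self, params):
        matrix = pt.transition_matrix(params)
        assert np.allclose(matrix.sum(axis=1), 1.0)
        assert (matrix >= 0).all()

    def test_expected_shares_reproduced(self, params):
        """The matrix encodes the requested changing fraction and shares."""
        matrix = pt.transition_matrix(params)
        marg = np.asarray(params.state_dist)
        mass = marg[:, None] * matrix
        changing = mass.sum() - np.trace(mass)
        assert changing == pytest.approx(params.changing_fraction)
        i = {s: k for k, s in enumerate(pt.STATES)}
        shares = {
            "activation": mass[i[pt.PAUSED], i[pt.ACTIVE]]
            + mass[i[pt.SILENT], i[pt.ACTIVE]],
            "silencing": mass[i[pt.ACTIVE], i[pt.PAUSED]]
            + mass[i[pt.ACTIVE], i[pt.SILENT]],
            "priming": mass[i[pt.SILENT], i[pt.PAUSED]],
            "archiving": mass[i[pt.PAUSED], i[pt.SILENT]],
        }
        for cat, expected in params.category_shares.items():
            assert shares[cat] / changing == pytest.approx(expected)
        direct = mass[i[pt.SILENT], i[pt.ACTIVE]] + mass[i[pt.ACTIVE], i[pt.SILENT]]
        assert direct / changing == pytest.approx(params.direct_share)

    def test_infeasible_shares_rejected(self):
        with pytest.raises(ValidationError):
            # more priming mass than there are silent loci
            pt.SimParams(state_dist=(0.7, 0.29, 0.01), changing_fraction=0.5)


class TestGenerateTruth:
    def test_identity_matrix_freezes_states(self, params):
        frozen = replace(params, changing_fraction=0.0)
        truth = pt.generate_truth(frozen)
        assert (truth["state_1"] == truth["state_2"]).all()

    def test_degenerate_distribution(self, params):
        all_active = replace(params, state_dist=(1.0, 0.0, 0.0),
                             changing_fraction=0.0)
        truth = pt.generate_truth(all_active)
        assert (truth["state_1"] == pt.ACTIVE).all()

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_changing_fraction_within_sampling_error(self, params, seed):
        """Binomial check: observed changing fraction near the configured 12%."""
        truth = pt.generate_truth(replace(params, seed=seed))
        changing = (truth["state_1"] != truth["state_2"]).mean()
        assert abs(changing - params.changing_fraction) < 0.02

    def test_lineage_tags_follow_transitions(self, study):
        truth = study.truth
        meso = truth.loc[truth["lineage"] == "mesoderm-like"]
        assert (meso["state_1"] == pt.PAUSED).all()
        assert (meso["state_2"] == pt.ACTIVE).all()
        ecto = truth.loc[truth["lineage"] == "ectoderm-like"]
        assert (ecto["state_2"] == pt.SILENT).all()

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValidationError):
            pt.SimParams(state_dist=(0.5, 0.5, 0.5))


class TestSimulateChip:
    def test_zero_noise_geometry(self, noiseless_study):
        """Initiating loci peak at exactly 2.0 log2 over the TSS probe."""
        study = noiseless_study
        table = study.chip[study.params.conditions[0]]
        cfg = pt.ChipCallerConfig()
        initiating = set(
            study.truth.loc[
                study.truth["state_1"].isin([pt.ACTIVE, pt.PAUSED]), "gene_id"
            ]
        )
        subset = set(study.truth["gene_id"].iloc[:200])
        table = table.loc[table["gene_id"].isin(subset)]
        for gene_id, group in table.groupby("gene_id"):
            profile = pt.build_metagene(group, cfg)
            at_tss = profile.log_ratios[profile.offsets == 0][0]
            expected = 2.0 if gene_id in initiating else 0.0
            assert at_tss == pytest.approx(expected, abs=1e-9)

    def test_probe_geometry(self, study):
        table = study.chip[study.params.conditions[0]]
        per_gene = table.groupby("gene_id")["offset"].agg(["size", "min", "max"])
        assert (per_gene["size"] == 33).all()
        assert (per_gene["min"] == -4000).all()
        assert (per_gene["max"] == 4000).all()

    def test_default_noise_call_error_rate(self, study):
        """Noise SD 0.3 against a 0.8 margin leaves calls near-perfect."""
        cfg = pt.ChipCallerConfig()
        for cond, col in zip(study.params.conditions, ("state_1", "state_2")):
            calls = pt.call_all_loci(study.chip[cond], cfg)
            merged = calls.merge(study.truth, on="gene_id")
            truth_bound = merged[col].isin([pt.ACTIVE, pt.PAUSED])
            assert (merged["bound"] != truth_bound).mean() < 0.01


class TestSimulateExpression:
    def test_zero_shift_yields_background_rate(self, params):
        null = replace(params, shift_control_sds=0.0, seed=21)
        study = pt.simulate_study(null)
        res = pt.run_pipeline(study.chip, study.expression)
        expressed_rate = res.transcripts["expressed"].mean()
        assert expressed_rate < 0.02

    def test_control_pool_size(self, study):
        for sample in study.expression:
            assert sample.control_pool.size == study.params.n_controls


class TestDeterminismAndFiles:
    def test_same_seed_same_bytes(self, tmp_path, params):
        small = replace(params, n_genes=60, n_controls=40)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        pt.write_study(pt.simulate_study(small), d1)
        pt.write_study(pt.simulate_study(small), d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_written_study_reloads(self, tmp_path, params):
        small = replace(params, n_genes=40, n_controls=30)
        study = pt.simulate_study(small)
        paths = pt.write_study(study, tmp_path)
        ann = pt.read_tss_annotation(paths["tss"])
        assert len(ann) == 40
        chip = pt.read_probe_signals(paths["chip_pluripotent"], ann)
        assert chip.attrs["n_dropped_unannotated"] == 0
        pd.testing.assert_frame_equal(
            chip, study.chip["pluripotent"], check_dtype=False, atol=1e-9
        )
        sample = pt.read_expression_sample(paths["expr_mesoderm_rep2"])
        assert sample.condition == "mesoderm" and sample.replicate == 2
        terms = pt.read_gene2go(paths["gene2go"])
        assert terms == study.terms
        truth = read_truth(paths["truth"])
        pd.testing.assert_frame_equal(truth, study.truth, check_dtype=False)

    def test_truth_round_trip(self, tmp_path, study):
        path = tmp_path / "truth.tsv"
        write_truth(study.truth, path)
        pd.testing.assert_frame_equal(
            read_truth(path), study.truth, check_dtype=False
        )
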