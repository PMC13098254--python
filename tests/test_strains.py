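"""Strain-model derivation, growth prediction scoring, reaction classes, MCA."""
import numpy as np
import pandas as pd
import pytest

from pangem.errors import ModelError
from pangem.network import Medium, MetabolicNetwork, Metabolite, Reaction
from pangem.orthology import bbh_map
from pangem.phenotype import GrowthCallMatrix
from pangem.strains import (
    StrainModel,
    classify_reactions,
    correspondence_analysis,
    derive_strain_model,
    mca_strains,
    predict_growth_matrix,
    score_predictions,
)
from .conftest import chain_network


def bbh_frame(pairs):
    return pd.DataFrame(
        [{"strain_gene": s, "pan_gene": p, "identity_fwd": 100.0, "identity_rev": 100.0} for s, p in pairs]
    , columns=["strain_gene", "pan_gene", "identity_fwd", "identity_rev"])


class TestDerivation:
    def test_full_bbh_coverage_keeps_model_identical(self):
        pan = chain_network(3, gene="g1")
        model = derive_strain_model(pan, bbh_frame([("s1", "g1")]), "S")
        assert set(model.network.reactions) == set(pan.reactions)
        assert model.removed_genes == [] and model.removed_reactions == []

    def test_missing_single_gene_removes_its_reaction(self):
        pan = chain_network(3, gene="g1")
        model = derive_strain_model(pan, bbh_frame([]), "S")
        assert "T_s" in model.removed_reactions
        assert "g1" in model.removed_genes
        assert "T_s" not in model.network.reactions

    def test_orphan_metabolites_pruned(self):
        pan = chain_network(1, gene="g1")
        model = derive_strain_model(pan, bbh_frame([]), "S")
        touched = {m for r in model.network.reactions.values() for m in r.metabolites}
        assert set(model.network.metabolites) == touched

    def test_pruning_is_monotone_in_gene_loss(self, small_world):
        pan = small_world.universal_network
        genes = sorted(pan.genes)
        kept_prev = None
        for k in range(len(genes), -1, -2):
            model = derive_strain_model(pan, bbh_frame([(g, g) for g in genes[:k]]), "S")
            kept = set(model.network.reactions)
            if kept_prev is not None:
                assert kept <= kept_prev
            kept_prev = kept

    def test_recovers_true_networks_for_every_strain(self, small_world):
        w = small_world
        for strain in w.strains:
            table = bbh_map(dict(w.proteomes[strain]), w.pan_proteins(), cutoff=60.0)
            model = derive_strain_model(w.universal_network, table, strain)
            truth = w.strain_true_network(strain)
            assert set(model.network.reactions) == set(truth.reactions)


class TestPrediction:
    def test_predictions_match_truth_in_synthetic_world(self, small_world):
        w = small_world
        models = []
        for strain in w.strains:
            table = bbh_map(dict(w.proteomes[strain]), w.pan_proteins(), cutoff=60.0)
            models.append(derive_strain_model(w.universal_network, table, strain))
        mat = predict_growth_matrix(models, [f"EX_{s}_e" for s in w.substrates], Medium(), 10.0)
        mat.calls.columns = pd.Index(w.substrates, name="substrate")
        pd.testing.assert_frame_equal(
            mat.calls.loc[w.strains, w.substrates], w.true_phenotype, check_names=False
        )

    def test_missing_exchange_predicts_no_growth(self):
        pan = chain_network(2, gene="g1")
        model = derive_strain_model(pan, bbh_frame([("s", "g1")]), "S")
        del model.network.reactions["EX_s_e"]
        mat = predict_growth_matrix([model], ["EX_s_e"], Medium(), 10.0)
        assert not bool(mat.calls.iloc[0, 0])


class TestScoring:
    def _mat(self, array, strains, subs):
        return GrowthCallMatrix.from_bool(pd.DataFrame(array, index=strains, columns=subs))

    def test_identical_matrices_perfect_score(self):
        m = self._mat([[True, False]], ["S"], ["a", "b"])
        score = score_predictions(m, m)
        assert (score.accuracy, score.false_positive_rate, score.false_negative_rate) == (1.0, 0.0, 0.0)

    def test_headline_rates_7fp_2fn_over_100(self):
        strains = [f"S{i}" for i in range(10)]
        subs = [f"c{j}" for j in range(10)]
        obs = np.zeros((10, 10), dtype=bool)
        obs[:, :5] = True
        pred = obs.copy()
        flat_fp = [(i, 5 + j) for i, j in [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 0), (6, 1)]]
        for i, j in flat_fp:
            pred[i, j] = True  # predicted growth, observed no-growth
        pred[0, 0] = pred[1, 1] = False  # two false negatives
        score = score_predictions(self._mat(pred, strains, subs), self._mat(obs, strains, subs))
        assert score.accuracy == pytest.approx(0.91)
        assert score.false_positive_rate == pytest.approx(0.07)
        assert score.false_negative_rate == pytest.approx(0.02)
        assert score.per_substrate["fp"].sum() == 7 and score.per_substrate["fn"].sum() == 2

    def test_all_disagree_scores_zero(self):
        a = self._mat([[True, False]], ["S"], ["a", "b"])
        b = self._mat([[False, True]], ["S"], ["a", "b"])
        assert score_predictions(a, b).accuracy == 0.0

    def test_empty_overlap_rejected(self):
        a = self._mat([[True]], ["S"], ["a"])
        b = self._mat([[True]], ["T"], ["b"])
        with pytest.raises(ValueError):
            score_predictions(a, b)


def toy_models(sets: dict[str, list[str]]) -> list[StrainModel]:
    """Strain models with prescribed reaction content over a shared universe."""
    universe = sorted({r for rs in sets.values() for r in rs})
    mets = [Metabolite("x_c", "c")]
    models = []
    for strain, rs in sets.items():
        rxns = [Reaction(r, {"x_c": 1.0 if r != "SINK" else -1.0}) for r in rs]
        if "SINK" not in rs:
            rxns.append(Reaction("SINK", {"x_c": -1.0}))
        net = MetabolicNetwork(strain, mets, rxns, "SINK")
        models.append(StrainModel(strain, net))
    return models


class TestClassification:
    def test_boundaries_at_098_and_010(self):
        # 50 strains: present in 49 -> 0.98 -> core; in 5 -> 0.10 -> accessory; in 4 -> 0.08 -> rare
        sets = {}
        for i in range(50):
            rs = ["SINK"]
            if i < 49:
                rs.append("R_core")
            if i < 5:
                rs.append("R_acc")
            if i < 4:
                rs.append("R_rare")
            sets[f"S{i:02d}"] = rs
        cls = classify_reactions(toy_models(sets)).classes
        assert cls["R_core"] == "core"
        assert cls["R_acc"] == "accessory"
        assert cls["R_rare"] == "rare"
        assert cls["SINK"] == "core"

    @pytest.mark.parametrize(
        "n_present, n_models, expected",
        [(24, 24, "core"), (2, 24, "rare"), (12, 24, "accessory")],
    )
    def test_frequency_classes(self, n_present, n_models, expected):
        sets = {f"S{i:02d}": (["R_x"] if i < n_present else []) for i in range(n_models)}
        cls = classify_reactions(toy_models(sets))
        assert cls.classes["R_x"] == expected

    def test_partition_property(self, small_world):
        w = small_world
        models = [StrainModel(s, w.strain_true_network(s)) for s in w.strains]
        cls = classify_reactions(models)
        assert set(cls.classes.unique()) <= {"core", "accessory", "rare"}
        assert cls.classes.index.is_unique
        assert len(cls.classes) == len({r for m in models for r in m.network.reactions})


class TestMca:
    def test_identical_strains_get_identical_coordinates(self):
        sets = {"A": ["R1", "R2"], "B": ["R1", "R2"], "C": ["R3"], "D": ["R1", "R3"]}
        res = mca_strains(toy_models(sets), 2)
        np.testing.assert_allclose(
            res.coordinates.loc["A"].to_numpy(), res.coordinates.loc["B"].to_numpy(), atol=1e-12
        )

    def test_inertia_fractions_non_increasing_and_bounded(self):
        sets = {"A": ["R1"], "B": ["R2"], "C": ["R3"], "D": ["R1", "R2"], "E": ["R2", "R3"]}
        res = mca_strains(toy_models(sets), 4)
        assert all(a >= b - 1e-12 for a, b in zip(res.inertia, res.inertia[1:]))
        assert res.inertia.sum() <= 1 + 1e-9

    def test_matches_independent_svd_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(4, 6))
        X[0, 0] = 1 - X[1, 0]  # ensure non-constant
        Z = np.concatenate([X, 1 - X], axis=1).astype(float)
        coords, inertia = correspondence_analysis(Z, 3)
        # oracle: re-derive from first principles with a fresh implementation
        Zo = Z[:, Z.sum(axis=0) > 0]
        P = Zo / Zo.sum()
        r, c = P.sum(1), P.sum(0)
        S = np.diag(r**-0.5) @ (P - np.outer(r, c)) @ np.diag(c**-0.5)
        U, sv, Vt = np.linalg.svd(S)
        expected = np.diag(r**-0.5) @ U[:, :3] * sv[:3]
        for j in range(coords.shape[1]):
            sign = np.sign(coords[0, j]) * np.sign(expected[0, j]) or 1.0
            np.testing.assert_allclose(coords[:, j], sign * expected[:, j], atol=1e-10)
        np.testing.assert_allclose(inertia, (sv**2 / (sv**2).sum())[:3], atol=1e-12)

    def test_two_block_world_separates_on_first_axis(self):
        sets = {f"A{i}": ["R1", "R2", "R3"] + [f"Ax{i}"] for i in range(3)}
        sets |= {f"B{i}": ["R4", "R5", "R6"] + [f"Bx{i}"] for i in range(3)}
        res = mca_strains(toy_models(sets), 1)
        axis = res.coordinates["axis_1"]
        a_signs = np.sign(axis[[f"A{i}" for i in range(3)]])
        b_signs = np.sign(axis[[f"B{i}" for i in range(3)]])
        assert len(set(a_signs)) == 1 and len(set(b_signs)) == 1
        assert a_signs.iloc[0] != b_signs.iloc[0]

    def test_constant_matrix_rejected(self):
        sets = {"A": ["R1"], "B": ["R1"], "C": ["R1"]}
        with pytest.raises(ModelError, match="inertia"):
            mca_strains(toy_models(sets), 2)
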