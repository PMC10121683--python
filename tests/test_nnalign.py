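import numpy as np
import pandas as pd
import pytest

from mhc2deconv.blosum import AMINO_ACIDS, BLOSUM50_SCALED, seq_to_indices
from mhc2deconv.datasets import Sample, partition_common_motif
from mhc2deconv.encoding import EncodingConfig, encode_groups, encode_pseudo
from mhc2deconv.nnalign import (
    EnsembleModel,
    Member,
    TrainingConfig,
    init_network,
    prepare_training_data,
    score_peptide,
    train,
    train_member,
)


def manual_offset_score(net, peptide, pseudo, offset, config=None):
    """Independent forward pass for one fixed core offset, built from the
    encoding contract definition rather than the vectorized machinery."""
    config = config or EncodingConfig()
    idx = seq_to_indices(peptide)
    core = BLOSUM50_SCALED[idx[offset : offset + 9]].reshape(-1)
    nfl = idx[max(0, offset - 3) : offset]
    cfl = idx[offset + 9 : offset + 12]
    nvec = BLOSUM50_SCALED[nfl].mean(axis=0) if nfl.size else np.zeros(20)
    cvec = BLOSUM50_SCALED[cfl].mean(axis=0) if cfl.size else np.zeros(20)
    lvec = np.zeros(10)
    lvec[min(max(len(peptide), 12), 21) - 12] = 1.0
    x = np.concatenate([core, nvec, cvec, lvec])
    z = net.W1np.astype(float) @ x + net.W1p.astype(float) @ encode_pseudo(pseudo) + net.b1
    h = 1.0 / (1.0 + np.exp(-z))
    a = net.W2[0].astype(float) @ h + net.b2[0]
    return float(1.0 / (1.0 + np.exp(-a)))


def random_peptide(rng, length):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


PSEUDO_A = "".join(AMINO_ACIDS[i % 20] for i in range(34))


class TestEncoding:
    def test_dimension_constant_across_lengths(self, rng):
        config = EncodingConfig()
        peptides = [random_peptide(rng, L) for L in (12, 15, 21)]
        groups = encode_groups(peptides, config)
        assert all(g.X.shape[2] == config.np_dim for g in groups)
        assert config.np_dim == 180 + 40 + 10

    def test_context_adds_block(self, rng):
        config = EncodingConfig(use_context=True)
        peptides = [random_peptide(rng, 13)]
        ctx = [random_peptide(rng, 12)]
        groups = encode_groups(peptides, config, ctx)
        assert groups[0].X.shape[2] == 180 + 40 + 10 + 240

    def test_missing_context_raises(self, rng):
        config = EncodingConfig(use_context=True)
        with pytest.raises(ValueError, match="context"):
            encode_groups([random_peptide(rng, 13)], config, [None])

    def test_short_peptide_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            encode_groups(["ACDEFGHI"], EncodingConfig())


class TestScorePeptide:
    def test_nine_mer_offset_zero(self, rng):
        net = init_network(40, EncodingConfig().np_dim, rng)
        score, off = score_peptide(net, "ACDEFGHIK", PSEUDO_A)
        assert off == 0
        assert 0.0 <= score <= 1.0

    def test_deterministic(self, rng):
        net = init_network(40, EncodingConfig().np_dim, rng)
        pep = random_peptide(rng, 16)
        assert score_peptide(net, pep, PSEUDO_A) == score_peptide(net, pep, PSEUDO_A)

    def test_short_peptide_rejected(self, rng):
        net = init_network(40, EncodingConfig().np_dim, rng)
        with pytest.raises(ValueError):
            score_peptide(net, "ACDEFGHI", PSEUDO_A)

    def test_argmax_matches_exhaustive_enumeration(self, rng):
        """1000 random cases: the reported (score, offset) equals a brute-force
        scan of manually encoded per-offset forward passes."""
        nets = [init_network(h, EncodingConfig().np_dim, rng) for h in (40, 60)]
        for _ in range(1000):
            net = nets[int(rng.integers(0, 2))]
            L = int(rng.integers(12, 22))
            pep = random_peptide(rng, L)
            pseudo = random_peptide(rng, 34)
            per_offset = [
                manual_offset_score(net, pep, pseudo, o) for o in range(L - 8)
            ]
            score, off = score_peptide(net, pep, pseudo)
            assert off == int(np.argmax(per_offset))
            assert score == pytest.approx(max(per_offset), abs=1e-5)


class TestEnsemblePrediction:
    def _model_from_nets(self, nets):
        from mhc2deconv.hla import PseudoSequenceTable

        members = [Member(n.W1np.shape[0], i, 0, n) for i, n in enumerate(nets)]
        return EnsembleModel(
            members=members,
            encoding=EncodingConfig(),
            training=TrainingConfig(),
            pseudo_table=PseudoSequenceTable({"DQA10101-DQB10501": PSEUDO_A}),
        )

    def test_single_member_equals_network_score(self, rng):
        net = init_network(40, EncodingConfig().np_dim, rng)
        model = self._model_from_nets([net])
        pep = random_peptide(rng, 15)
        expected, _ = score_peptide(net, pep, PSEUDO_A)
        assert model.predict(pep, "DQA10101-DQB10501") == pytest.approx(expected, abs=1e-6)

    def test_mean_over_members(self, rng):
        nets = [init_network(40, EncodingConfig().np_dim, rng) for _ in range(7)]
        model = self._model_from_nets(nets)
        pep = random_peptide(rng, 14)
        member_scores = [score_peptide(n, pep, PSEUDO_A)[0] for n in nets]
        assert model.predict(pep, "DQA10101-DQB10501") == pytest.approx(
            np.mean(member_scores), abs=1e-6
        )

    def test_empty_ensemble_rejected(self):
        from mhc2deconv.hla import PseudoSequenceTable

        with pytest.raises(ValueError, match="empty"):
            EnsembleModel(
                members=[],
                encoding=EncodingConfig(),
                training=TrainingConfig(),
                pseudo_table=PseudoSequenceTable(),
            )

    def test_scores_in_unit_interval(self, tiny_model, rng):
        peptides = [random_peptide(rng, int(rng.integers(12, 22))) for _ in range(50)]
        scores = tiny_model.score_matrix(peptides, tiny_model.pseudo_table.names()[:2])
        assert np.all(scores >= 0.0) and np.all(scores <= 1.0)


def _micro_data(rng, n_pos=60, ma=True):
    """Two molecules, one SA sample each (+ optionally one MA sample)."""
    from mhc2deconv.hla import PseudoSequenceTable

    pseudo = PseudoSequenceTable(
        {"MOLA": "".join(rng.choice(list(AMINO_ACIDS), 34)),
         "MOLB": "".join(rng.choice(list(AMINO_ACIDS), 34))}
    )
    rows = []
    for sid, mols in (("S1", ("MOLA",)), ("S2", ("MOLB",))):
        for _ in range(n_pos):
            rows.append((random_peptide(rng, int(rng.integers(12, 18))), 1.0, sid))
        for _ in range(n_pos):
            rows.append((random_peptide(rng, int(rng.integers(12, 18))), 0.0, sid))
    samples = {"S1": Sample("S1", ("MOLA",)), "S2": Sample("S2", ("MOLB",))}
    if ma:
        for _ in range(n_pos):
            rows.append((random_peptide(rng, int(rng.integers(12, 18))), 1.0, "M1"))
            rows.append((random_peptide(rng, int(rng.integers(12, 18))), 0.0, "M1"))
        samples["M1"] = Sample("M1", ("MOLA", "MOLB"))
    el = pd.DataFrame(rows, columns=["peptide", "target", "sample_id"])
    part = partition_common_motif(el["peptide"], k=5, seed=0)
    return el, samples, part, pseudo


class TestTraining:
    def test_untrained_ensemble_is_random_predictor(self, rng):
        el, samples, part, pseudo = _micro_data(rng, n_pos=125, ma=False)
        cfg = TrainingConfig(epochs=0, burn_in_epochs=0, n_seeds=1, hidden_sizes=(40,), seed=0)
        model = train(el, None, samples, part, pseudo, config=cfg)
        peptides = el["peptide"].tolist()
        scores = model.score_matrix(peptides, ["MOLA"])[:, 0]
        from mhc2deconv.evaluation import auc

        value = auc(scores[el["target"] == 1], scores[el["target"] == 0])
        assert value == pytest.approx(0.5, abs=0.1)

    def test_burn_in_contract(self, rng):
        """Zero gradient updates from MA eluted-ligand records during the
        burn-in epochs; MA records train afterwards."""
        el, samples, part, pseudo = _micro_data(rng, n_pos=40)
        cfg = TrainingConfig(
            epochs=25, burn_in_epochs=20, n_seeds=1, hidden_sizes=(40,), seed=0
        )
        data = prepare_training_data(el, None, samples, part, pseudo)
        counts_by_epoch = {}
        train_member(
            data, 40, 0, 0, cfg, hook=lambda epoch, counts: counts_by_epoch.update({epoch: counts})
        )
        assert all(counts_by_epoch[e]["MA_EL"] == 0 for e in range(1, 21))
        assert all(counts_by_epoch[e]["MA_EL"] > 0 for e in range(21, 26))
        assert all(counts_by_epoch[e]["SA_EL"] > 0 for e in range(1, 26))

    def test_reproducible_weights(self, rng):
        el, samples, part, pseudo = _micro_data(rng, n_pos=30)
        cfg = TrainingConfig(epochs=3, burn_in_epochs=1, n_seeds=1, hidden_sizes=(40,), seed=9)
        data = prepare_training_data(el, None, samples, part, pseudo)
        a = train_member(data, 40, 0, 0, cfg)
        b = train_member(data, 40, 0, 0, cfg)
        np.testing.assert_array_equal(a.W1np, b.W1np)
        np.testing.assert_array_equal(a.W1p, b.W1p)
        np.testing.assert_array_equal(a.W2, b.W2)

    def test_unknown_molecule_fails_before_training(self, rng):
        el, samples, part, _ = _micro_data(rng, n_pos=20, ma=False)
        from mhc2deconv.hla import PseudoSequenceTable

        cfg = TrainingConfig(epochs=1, burn_in_epochs=0, n_seeds=1, hidden_sizes=(40,))
        with pytest.raises(KeyError, match="MOL"):
            train(el, None, samples, part, PseudoSequenceTable(), config=cfg)

    def test_sa_motif_recovery(self, tiny_model, tiny_study):
        """A single-motif SA sample yields a deconvoluted PSSM matching the
        planted one."""
        from mhc2deconv.deconvolution import build_pssm, cores_from_annotations
        from mhc2deconv.deconvolution import assign_restriction

        mol = tiny_study.sa_molecules[0]
        pos = tiny_study.el[
            (tiny_study.el["sample_id"] == "SA1") & (tiny_study.el["target"] == 1)
        ]
        ann = assign_restriction(
            tiny_model, tiny_study.samples["SA1"], pos["peptide"].tolist()
        )
        pssm = build_pssm(cores_from_annotations(ann[~ann["is_trash"]]))
        pcc = np.corrcoef(
            tiny_study.motifs[mol].matrix.reshape(-1), pssm.freq.reshape(-1)
        )[0, 1]
        assert pcc > 0.8

    def test_ma_deconvolution_small_scale(self, tiny_model, tiny_study):
        """Most MA positives return to their generating molecule even at this
        reduced problem size (the full-size study is held to a stricter bar)."""
        from mhc2deconv.deconvolution import assign_restriction
        from mhc2deconv.pipeline import ma_assignment_accuracy

        sample = tiny_study.samples["MA1"]
        recs = tiny_study.el[tiny_study.el["sample_id"] == "MA1"]
        ann = assign_restriction(
            tiny_model, sample, recs["peptide"].tolist(), targets=recs["target"].to_numpy()
        )
        acc = ma_assignment_accuracy(ann, tiny_study)
        assert acc > 0.75


class TestSerialization:
    def test_round_trip(self, tiny_model, tmp_path, rng):
        path = tmp_path / "model.json"
        tiny_model.save(path)
        back = EnsembleModel.load(path)
        peptides = [random_peptide(rng, 15) for _ in range(10)]
        mols = tiny_model.pseudo_table.names()[:2]
        np.testing.assert_allclose(
            tiny_model.score_matrix(peptides, mols),
            back.score_matrix(peptides, mols),
            atol=1e-12,
        )
        assert set(back.calibrations) == set(tiny_model.calibrations)

    def test_unrecognized_container_rejected(self, tmp_path):
        path = tmp_path / "bogus.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="container"):
            EnsembleModel.load(path)
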