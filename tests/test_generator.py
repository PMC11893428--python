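import numpy as np
import pytest

from nanolibkit import generator as G
from nanolibkit.fixtures import GERMLINES
from nanolibkit.numbering import extract_regions, number_sequence
from nanolibkit.seqio import SequenceRecord, validate_sequence
from nanolibkit.simdata import RepertoireConfig, simulate_repertoire

TINY = dict(d_model=32, n_layers=2, n_heads=2, d_ff=64, max_len=80, rank=2)


@pytest.fixture()
def tiny_model():
    spec = G.LoraModelSpec(germlines=GERMLINES, **TINY)
    return G.build_model(spec, seed=0)


@pytest.fixture(scope="module")
def tiny_records():
    records = []
    for gi, g in enumerate(GERMLINES):
        recs, _ = simulate_repertoire(RepertoireConfig(germline=g, n=30, seed=gi))
        records += recs
    # trim to fit the tiny context window
    return [
        SequenceRecord(id=r.id, seq=r.seq[:60], germline_label=r.germline_label)
        for r in records
    ]


class TestLoraMechanics:
    def test_zero_init_equivalence_is_exact(self, tiny_model):
        """With B = 0 the adapted model's logits equal the base model's
        bitwise: the low-rank delta A x B vanishes identically."""
        tok = tiny_model.tokenizer
        tokens = np.array([tok.encode("EVQLVESGG", "IGHV3-3*01")])
        base_logits, _ = tiny_model.net.forward(tokens)
        G.attach_lora(tiny_model, seed=1)
        adapted_logits, _ = tiny_model.net.forward(tokens)
        assert np.array_equal(base_logits, adapted_logits)

    def test_rank_too_large_rejected(self):
        with pytest.raises(ValueError):
            G.LoraModelSpec(germlines=GERMLINES, d_model=8, d_ff=8, rank=8)

    def test_trainable_parameter_count_closed_form(self, tiny_model):
        G.attach_lora(tiny_model, seed=0)
        d, f, r = TINY["d_model"], TINY["d_ff"], TINY["rank"]
        per_layer = 4 * (d * r + r * d) + 2 * (d * r + r * f) + (f * r + r * d)
        expected = TINY["n_layers"] * per_layer
        assert tiny_model.net.n_lora_params() == expected
        frac = G.trainable_fraction(tiny_model)
        assert frac == pytest.approx(
            expected / (tiny_model.net.n_base_params() + expected)
        )

    def test_no_adapters_means_zero_trainable_fraction(self, tiny_model):
        assert G.trainable_fraction(tiny_model) == 0.0

    def test_doubling_rank_doubles_trainable_count(self):
        counts = []
        for r in (2, 4):
            spec = G.LoraModelSpec(germlines=GERMLINES, **{**TINY, "rank": r})
            m = G.attach_lora(G.build_model(spec, seed=0), seed=0)
            counts.append(m.net.n_lora_params())
        assert counts[1] == 2 * counts[0]

    def test_default_spec_trainable_fraction_near_six_percent(self):
        model = G.attach_lora(
            G.build_model(G.LoraModelSpec(germlines=GERMLINES), seed=0), seed=0
        )
        assert G.trainable_fraction(model) == pytest.approx(0.06, abs=0.01)


class TestTraining:
    def test_freeze_contract_and_loss_decrease(self, tiny_model, tiny_records):
        G.pretrain(tiny_model, tiny_records, epochs=1, seed=0)
        checksum_before = tiny_model.net.base_checksum()
        trained = G.train(tiny_model, tiny_records, epochs=3, lr=5e-3, seed=0)
        assert trained.base_checksum_pre == trained.base_checksum_post
        assert tiny_model.net.base_checksum() == checksum_before
        # loss non-increasing within tolerance
        log = trained.training_log
        assert all(b <= a + 0.05 for a, b in zip(log, log[1:]))

    def test_training_reduces_heldout_nll(self, tiny_records):
        """Adapter training lowers held-out next-token negative
        log-likelihood relative to the zero-initialised adapters."""
        from nanolibkit._nn import cross_entropy

        spec = G.LoraModelSpec(germlines=GERMLINES, **TINY)
        model = G.build_model(spec, seed=0)
        train_set, heldout = tiny_records[:48], tiny_records[48:]
        tok = model.tokenizer

        def heldout_nll():
            encoded = [tok.encode(r.seq, r.germline_label) for r in heldout]
            T = max(len(e) for e in encoded)
            tokens = np.full((len(encoded), T), tok.PAD, dtype=np.int64)
            for j, e in enumerate(encoded):
                tokens[j, : len(e)] = e
            logits, _ = model.net.forward(tokens[:, :-1])
            mask = (tokens[:, 1:] != tok.PAD).astype(np.float32)
            loss, _ = cross_entropy(logits, tokens[:, 1:], mask)
            return loss

        G.attach_lora(model, seed=0)
        before = heldout_nll()
        G.train(model, train_set, epochs=3, lr=5e-3, seed=0)
        assert heldout_nll() < before

    def test_same_seed_identical_adapters(self, tiny_records):
        states = []
        for _ in range(2):
            spec = G.LoraModelSpec(germlines=GERMLINES, **TINY)
            model = G.build_model(spec, seed=3)
            trained = G.train(model, tiny_records[:20], epochs=2, seed=5)
            states.append(trained.adapter_state)
        for name in states[0]:
            assert np.array_equal(states[0][name][0], states[1][name][0])
            assert np.array_equal(states[0][name][1], states[1][name][1])

    def test_unlabeled_record_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="germline"):
            G.train(tiny_model, [SequenceRecord(id="x", seq="EVQLV")], epochs=1)

    def test_empty_dataset_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            G.train(tiny_model, [], epochs=1)


class TestGenerate:
    def test_n_zero_gives_empty_list(self, tiny_model):
        G.attach_lora(tiny_model, seed=0)
        assert G.generate(tiny_model, "IGHV3-3*01", n=0) == []

    def test_same_seed_identical_output(self, tiny_model, tiny_records):
        G.pretrain(tiny_model, tiny_records[:20], epochs=1, seed=0)
        G.train(tiny_model, tiny_records[:20], epochs=1, seed=0)
        a = G.generate(tiny_model, "IGHV3-3*01", n=5, seed=11)
        b = G.generate(tiny_model, "IGHV3-3*01", n=5, seed=11)
        assert [r.seq for r in a] == [r.seq for r in b]

    def test_outputs_unique_valid_and_tagged(self, tiny_model, tiny_records):
        G.train(tiny_model, tiny_records[:20], epochs=1, seed=0)
        out = G.generate(tiny_model, "IGHV3S53*01", n=8, seed=2)
        seqs = [r.seq for r in out]
        assert len(set(seqs)) == len(seqs)
        for rec in out:
            assert validate_sequence(rec.seq).ok
            assert rec.germline_label == "IGHV3S53*01"

    def test_unknown_tag_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            G.generate(tiny_model, "IGHV9-99*01", n=1)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tiny_model, tiny_records, tmp_path):
        G.train(tiny_model, tiny_records[:10], epochs=1, seed=0)
        G.save_checkpoint(tiny_model, tmp_path / "ckpt")
        loaded = G.load_checkpoint(tmp_path / "ckpt")
        tok = tiny_model.tokenizer
        tokens = np.array([tok.encode("EVQLVESGG", "IGHV3-3*01")])
        a, _ = tiny_model.net.forward(tokens)
        b, _ = loaded.net.forward(tokens)
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def annotations(ref_by_name):
    records, _ = simulate_repertoire(
        RepertoireConfig(germline="IGHV3-3*01", n=150, seed=21)
    )
    ref = ref_by_name["IGHV3-3*01"]
    return [extract_regions(number_sequence(r, ref)) for r in records]


class TestPssmBaseline:
    def test_fit_on_one_sequence_is_near_point_mass(self, annotations):
        # with pseudo-count 0.01 a single observation gives 1.01/1.2 = 0.84
        # on the observed residue and 0.0083 elsewhere
        pssm = G.fit_pssm(annotations[:1], "IGHV3-3*01")
        for region in ("CDR1", "CDR2", "CDR3"):
            for mat in pssm.tables[region].values():
                assert np.allclose(mat.sum(axis=1), 1.0)
                assert mat.max(axis=1) == pytest.approx(
                    np.full(mat.shape[0], 1.01 / 1.2)
                )

    def test_columns_normalised_and_positive(self, annotations):
        pssm = G.fit_pssm(annotations, "IGHV3-3*01")
        for region in pssm.tables.values():
            for mat in region.values():
                assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-9)
                assert (mat > 0).all()

    def test_sample_fit_roundtrip_recovers_frequencies(self, annotations, ref_by_name):
        """Fitting on a large sample drawn from a PSSM recovers the source
        column frequencies (law of large numbers)."""
        source = G.fit_pssm(annotations, "IGHV3-3*01")
        samples = G.sample_pssm(source, n=4000, seed=3)
        ref = ref_by_name["IGHV3-3*01"]
        sample_anns = [
            extract_regions(number_sequence(r, ref)) for r in samples
        ]
        refit = G.fit_pssm(sample_anns, "IGHV3-3*01")
        # compare the dominant CDR3 stratum
        L = max(
            source.cdr3_length_distribution,
            key=source.cdr3_length_distribution.get,
        )
        a, b = source.tables["CDR3"][L], refit.tables["CDR3"][L]
        # ~800 samples land in the dominant stratum; per-column L1 error
        # then concentrates below ~0.2
        l1 = np.abs(a - b).sum(axis=1)
        assert l1.max() <= 0.2
        assert l1.mean() <= 0.1

    def test_samples_always_validate(self, annotations):
        pssm = G.fit_pssm(annotations, "IGHV3-3*01")
        for rec in G.sample_pssm(pssm, n=50, seed=5):
            assert validate_sequence(rec.seq).ok
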