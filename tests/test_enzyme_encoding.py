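"""Enzyme representations: pooling, PCA context, task-token encoder."""

import numpy as np
import pytest
from rdkit import Chem
from sklearn.metrics import roc_auc_score

from esp.enzyme_encoding import (IdentityEncoder, MiniTransformer, PCAContext,
                                 TaskTokenEncoder, apply_pca,
                                 composition_embeddings, fit_pca,
                                 identity_profile_vectors,
                                 load_enzyme_vectors, load_residue_embeddings,
                                 mean_pool, save_enzyme_vectors,
                                 save_residue_embeddings)
from esp.molecule_features import compute_ecfp
from esp.data_io import EnzymeRecord, MoleculeRecord
from esp.synthetic_data import gen_diverse_molecules


class TestMeanPool:
    def test_constant_rows(self):
        v = np.array([1.0, -2.0, 3.0])
        assert np.array_equal(mean_pool(np.tile(v, (5, 1))), v)

    def test_two_rows(self):
        m = np.vstack([np.zeros(4), np.full(4, 2.0)])
        assert np.array_equal(mean_pool(m), np.ones(4))

    def test_matches_column_mean_oracle(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, (7, 5))
        oracle = np.array([m[:, j].sum() / 7 for j in range(5)])
        assert np.allclose(mean_pool(m), oracle)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mean_pool(np.zeros((0, 5)))


class TestPCAContext:
    def test_output_dim_default_50(self):
        rng = np.random.default_rng(0)
        vectors = rng.normal(0, 1, (60, 80))
        proj = fit_pca(vectors)  # k defaults to 50
        assert apply_pca(proj, vectors[0]).shape == (50,)
        assert proj.components_.shape == (50, 80)

    def test_explained_variance_matches_eigen_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (40, 60))
        proj = fit_pca(X, k=10)
        cov = np.cov(X, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(proj.explained_variance_, eigvals[:10])
        # variances non-increasing, components orthonormal
        assert np.all(np.diff(proj.explained_variance_) <= 1e-9)
        assert np.allclose(proj.components_ @ proj.components_.T, np.eye(10),
                           atol=1e-9)

    def test_exact_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (30, 5)) @ rng.normal(0, 1, (5, 20))
        proj = fit_pca(X, k=5)
        Z = proj.transform(X)
        recon = Z @ proj.components_ + proj.mean_
        assert np.allclose(recon, X, atol=1e-8)

    def test_train_only_guard(self):
        vectors = np.random.default_rng(0).normal(0, 1, (20, 10))
        with pytest.raises(ValueError, match="training partition"):
            fit_pca(vectors, k=5, partition_tags=["train"] * 19 + ["test"])
        proj = fit_pca(vectors, k=5, partition_tags=["train"] * 20)
        assert proj.components_.shape == (5, 10)

    def test_apply_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            PCAContext(5).transform(np.zeros(10))


class TestTaskToken:
    def test_token_initialized_to_residue_mean(self):
        enc = TaskTokenEncoder(base_encoder=IdentityEncoder())
        enc.base_encoder.embed = MiniTransformer(dim=8, seed=0).embed
        vec = enc.encode("ACDEFGHIKL")
        tokens = MiniTransformer(dim=8, seed=0).embed("ACDEFGHIKL")
        assert np.allclose(vec.data.ravel(), tokens.data.mean(axis=0))

    def test_ablation_equals_pooled_final_states(self):
        base = MiniTransformer(dim=8, seed=1)
        enc = TaskTokenEncoder(base_encoder=base, use_extra_token=False)
        vec = enc.encode("ACDEFGHIKL")
        manual = base.forward(base.embed("ACDEFGHIKL")).data.mean(axis=0)
        assert np.allclose(vec.data.ravel(), manual)

    def test_truncation_warns(self):
        base = MiniTransformer(dim=8, max_len=5, seed=0)
        with pytest.warns(UserWarning, match="truncated"):
            base.embed("ACDEFGHIKL")

    def test_single_class_raises(self):
        enc = TaskTokenEncoder(base_encoder=MiniTransformer(dim=8, seed=0),
                               epochs=1)
        with pytest.raises(ValueError, match="degenerate"):
            enc.fit(["ACDE", "MKLV"], np.zeros((2, 16)), np.ones(2))


@pytest.fixture(scope="module")
def family_benchmark():
    """Planted rule: binder iff the enzyme carries the family motif AND the
    molecule carries a carboxylic acid."""
    rng = np.random.default_rng(0)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    motif = "HHWWHH"

    def mkseq(has_motif):
        s = [aa[i] for i in rng.integers(0, 20, 40)]
        if has_motif:
            p = int(rng.integers(5, 40 - len(motif) - 5))
            s[p:p + len(motif)] = list(motif)
        return "".join(s)

    n_enz = 16
    seqs = [mkseq(i < n_enz // 2) for i in range(n_enz)]
    has = np.array([i < n_enz // 2 for i in range(n_enz)], dtype=float)
    mols = gen_diverse_molecules(12)
    acid = Chem.MolFromSmarts("C(=O)[OX2H1]")
    mol_motif = np.array([float(m.parsed.HasSubstructMatch(acid)) for m in mols])
    fps = np.array([compute_ecfp(m, 256, 2) for m in mols], dtype=float)
    E, M = np.meshgrid(np.arange(n_enz), np.arange(len(mols)), indexing="ij")
    E, M = E.ravel(), M.ravel()
    y = (has[E] * mol_motif[M]).astype(float)
    perm = rng.permutation(len(y))
    cut = int(0.75 * len(y))
    return seqs, fps, E, M, y, perm[:cut], perm[cut:], has


class TestFineTuning:
    def test_recovers_family_motif_rule(self, family_benchmark):
        seqs, fps, E, M, y, tr, te, _ = family_benchmark
        enc = TaskTokenEncoder(base_encoder=MiniTransformer(dim=32, seed=0),
                               head_dims=(64, 16), epochs=8, seed=0)
        enc.fit([seqs[E[i]] for i in tr], fps[M[tr]], y[tr])
        assert enc.history_[-1] < enc.history_[0]
        scores = enc.predict_proba([seqs[E[i]] for i in te], fps[M[te]])
        assert roc_auc_score(y[te], scores) > 0.85

    def test_extra_token_not_worse_than_ablation(self, family_benchmark):
        seqs, fps, E, M, y, tr, te, _ = family_benchmark

        def auc(use_token, seed):
            enc = TaskTokenEncoder(
                base_encoder=MiniTransformer(dim=32, seed=seed),
                head_dims=(64, 16), use_extra_token=use_token, epochs=8,
                seed=seed)
            enc.fit([seqs[E[i]] for i in tr], fps[M[tr]], y[tr])
            s = enc.predict_proba([seqs[E[i]] for i in te], fps[M[te]])
            return roc_auc_score(y[te], s)

        seeds = range(5)
        token = np.mean([auc(True, s) for s in seeds])
        ablation = np.mean([auc(False, s) for s in seeds])
        assert token >= ablation

    def test_extracted_vectors_separate_families(self, family_benchmark):
        seqs, fps, E, M, y, tr, _, has = family_benchmark
        enc = TaskTokenEncoder(base_encoder=MiniTransformer(dim=32, seed=0),
                               head_dims=(64, 16), epochs=8, seed=0)
        enc.fit([seqs[E[i]] for i in tr], fps[M[tr]], y[tr])
        table = enc.transform({f"E{i}": s for i, s in enumerate(seqs)})
        assert set(table) == {f"E{i}" for i in range(len(seqs))}
        vecs = np.array([table[f"E{i}"] for i in range(len(seqs))])
        within, between = [], []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = np.linalg.norm(vecs[i] - vecs[j])
                (within if has[i] == has[j] else between).append(d)
        assert np.mean(between) > np.mean(within)
        # repeated extraction is deterministic
        again = enc.transform({"E0": seqs[0]})
        assert np.array_equal(again["E0"], table["E0"])


class TestEmbeddingSources:
    def test_composition_embeddings_shape_and_determinism(self):
        a = composition_embeddings("ACDEFG", dim=16, seed=0)
        b = composition_embeddings("ACDEFG", dim=16, seed=0)
        assert a.shape == (6, 16)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            composition_embeddings("")

    def test_identity_profile_vectors(self):
        enzymes = [EnzymeRecord("a", "ACDEFGHIKL"),
                   EnzymeRecord("b", "ACDEFGHIKL"),
                   EnzymeRecord("c", "WWWWYYYYWW")]
        vecs = identity_profile_vectors(enzymes, anchor_spacing=1)
        assert vecs["a"].shape == (3,)
        assert vecs["a"][0] == 1.0  # self-identity against own anchor
        assert vecs["a"][1] == 1.0 and vecs["b"][0] == 1.0
        assert vecs["c"][0] < 0.5

    def test_residue_embedding_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        tables = {"E1": rng.normal(0, 1, (5, 4)), "E2": rng.normal(0, 1, (3, 4))}
        save_residue_embeddings(tmp_path, tables)
        loaded = load_residue_embeddings(tmp_path)
        for k in tables:
            assert np.allclose(loaded[k], tables[k])

    def test_residue_embedding_validation(self, tmp_path):
        save_residue_embeddings(tmp_path, {"E1": np.zeros((4, 3))})
        manifest = (tmp_path / "manifest.csv").read_text()
        (tmp_path / "manifest.csv").write_text(manifest.replace("4,3", "5,3"))
        with pytest.raises(ValueError, match="E1"):
            load_residue_embeddings(tmp_path)
        bad = np.zeros((2, 2))
        bad[0, 0] = np.nan
        save_residue_embeddings(tmp_path / "nan", {"E2": bad})
        with pytest.raises(ValueError, match="E2"):
            load_residue_embeddings(tmp_path / "nan")

    def test_enzyme_vector_roundtrip(self, tmp_path):
        vecs = {"E1": np.arange(4.0), "E2": np.ones(4)}
        save_enzyme_vectors(tmp_path / "v.csv", vecs)
        loaded = load_enzyme_vectors(tmp_path / "v.csv")
        for k in vecs:
            assert np.allclose(loaded[k], vecs[k])
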