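"""PDB parsing, ensemble statistics and the synthetic-family generator."""

import io

import numpy as np
import pytest

from eigas.structures import (
    CalphaChain,
    PDBFormatError,
    ensemble_stats,
    generate_synthetic_family,
    read_calpha_trace,
    read_family_labels,
    write_calpha_pdb,
    write_family_labels,
)

TWO_RESIDUE_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00 20.00           C
END
"""

NO_CA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  O   ALA A   1       1.000   0.000   0.000  1.00 10.00           O
END
"""


class TestReadCalphaTrace:
    def test_coordinates_and_bfactors_copied_verbatim(self):
        chain = read_calpha_trace(io.StringIO(TWO_RESIDUE_PDB))
        assert len(chain) == 2
        np.testing.assert_array_equal(chain.coords[0], [0.0, 0.0, 0.0])
        np.testing.assert_array_equal(chain.coords[1], [3.8, 0.0, 0.0])
        np.testing.assert_array_equal(chain.bfactors, [10.0, 20.0])

    def test_no_ca_atoms_is_an_error(self):
        with pytest.raises(PDBFormatError, match="no CA"):
            read_calpha_trace(io.StringIO(NO_CA_PDB))

    def test_first_model_of_duplicated_ensemble_equals_single_model(self):
        body = TWO_RESIDUE_PDB.replace("END\n", "")
        multi = f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{body}ENDMDL\nEND\n"
        single = read_calpha_trace(io.StringIO(TWO_RESIDUE_PDB))
        first = read_calpha_trace(io.StringIO(multi), model_policy="first")
        np.testing.assert_array_equal(first.coords, single.coords)
        np.testing.assert_array_equal(first.bfactors, single.bfactors)

    def test_model_policy_all_returns_one_chain_per_model(self):
        body = TWO_RESIDUE_PDB.replace("END\n", "")
        shifted = body.replace("3.800", "7.600")
        multi = f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{shifted}ENDMDL\nEND\n"
        models = read_calpha_trace(io.StringIO(multi), model_policy="all")
        assert len(models) == 2
        assert models[1].coords[1, 0] == pytest.approx(7.6)
        indexed = read_calpha_trace(io.StringIO(multi), model_policy="index", model_index=1)
        np.testing.assert_array_equal(indexed.coords, models[1].coords)

    def test_multiple_chains_require_explicit_selection(self):
        two_chains = TWO_RESIDUE_PDB.replace("END\n", "") + (
            "ATOM      3  CA  ALA B   1       9.000   0.000   0.000  1.00 30.00           C\n"
            "END\n"
        )
        with pytest.raises(PDBFormatError, match="chain"):
            read_calpha_trace(io.StringIO(two_chains))
        picked = read_calpha_trace(io.StringIO(two_chains), chain_id="B")
        assert len(picked) == 1
        assert picked.bfactors[0] == 30.0

    def test_altloc_keeps_highest_occupancy_conformer(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 11.00           C\n"
            "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00 20.00           C\n"
            "END\n"
        )
        chain = read_calpha_trace(io.StringIO(text))
        assert len(chain) == 2
        assert chain.coords[0, 0] == pytest.approx(5.0)  # occupancy 0.60 wins

    def test_write_read_round_trip_is_exact(self):
        chain = CalphaChain(
            chain_id="A",
            coords=np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [5.1, 2.2, -1.5]]),
            bfactors=np.array([10.0, 20.0, 15.25]),
        )
        buf = io.StringIO()
        write_calpha_pdb(chain, buf)
        again = read_calpha_trace(io.StringIO(buf.getvalue()))
        np.testing.assert_array_equal(again.coords, chain.coords)
        np.testing.assert_array_equal(again.bfactors, chain.bfactors)
        # second round trip is bit-identical
        buf2 = io.StringIO()
        write_calpha_pdb(again, buf2)
        assert buf2.getvalue() == buf.getvalue()

    def test_multi_model_round_trip(self):
        fam = generate_synthetic_family(3, 10, template_seed=1, jitter_sd=0.5, member_seed=2)
        buf = io.StringIO()
        write_calpha_pdb(fam, buf)
        models = read_calpha_trace(io.StringIO(buf.getvalue()), model_policy="all")
        assert len(models) == 3
        for written, original in zip(models, fam):
            np.testing.assert_allclose(written.coords, original.coords, atol=5e-4)


class TestChainInvariants:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CalphaChain("A", np.zeros((2, 3)), np.zeros(3))

    def test_negative_bfactor_rejected(self):
        with pytest.raises(ValueError):
            CalphaChain("A", np.zeros((1, 3)), np.array([-1.0]))


class TestEnsembleStats:
    def _chain(self, coords):
        coords = np.asarray(coords, float)
        return CalphaChain("m", coords, np.zeros(len(coords)))

    def test_identical_models_have_zero_variance(self):
        c = [[0, 0, 0], [3.8, 0, 0]]
        stats = ensemble_stats([self._chain(c)] * 3)
        np.testing.assert_array_equal(stats.variance, 0.0)
        np.testing.assert_array_equal(stats.mean, c)

    def test_two_model_sample_variance(self):
        a = self._chain([[0, 0, 0]])
        b = self._chain([[2, 0, 0]])
        stats = ensemble_stats([a, b])
        assert stats.mean[0, 0] == 1.0
        assert stats.variance[0, 0] == 2.0  # (0-1)^2 + (2-1)^2 over n-1 = 1

    def test_variance_zero_iff_models_coincide(self):
        a = self._chain([[0, 0, 0]])
        b = self._chain([[0, 0, 1e-6]])
        assert np.any(ensemble_stats([a, b]).variance > 0)

    def test_single_model_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            ensemble_stats([self._chain([[0, 0, 0]])])

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="same length"):
            ensemble_stats([self._chain([[0, 0, 0]]), self._chain([[0, 0, 0], [1, 0, 0]])])

    def test_monte_carlo_means_match_generating_distribution(self):
        rng = np.random.default_rng(42)
        true_mean = np.array([[1.0, -2.0, 3.0], [0.0, 5.0, -1.0]])
        sd = 0.7
        models = [
            self._chain(true_mean + rng.normal(scale=sd, size=true_mean.shape))
            for _ in range(20)
        ]
        stats = ensemble_stats(models)
        se = sd / np.sqrt(20)
        assert np.all(np.abs(stats.mean - true_mean) < 3 * se)


class TestSyntheticFamilies:
    def test_zero_jitter_members_equal_template(self):
        fam = generate_synthetic_family(3, 12, template_seed=5, jitter_sd=0.0, member_seed=9)
        for member in fam[1:]:
            np.testing.assert_array_equal(member.coords, fam[0].coords)

    def test_same_seeds_are_bit_identical(self):
        kw = dict(n_members=3, length=15, template_seed=3, jitter_sd=0.4, member_seed=8)
        a = generate_synthetic_family(**kw)
        b = generate_synthetic_family(**kw)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.coords, y.coords)
            np.testing.assert_array_equal(x.bfactors, y.bfactors)

    def test_members_invariant_to_requested_count(self):
        few = generate_synthetic_family(2, 15, template_seed=3, jitter_sd=0.4, member_seed=8)
        many = generate_synthetic_family(5, 15, template_seed=3, jitter_sd=0.4, member_seed=8)
        for x, y in zip(few, many):
            np.testing.assert_array_equal(x.coords, y.coords)

    def test_backbone_geometry(self):
        fam = generate_synthetic_family(1, 30, template_seed=7, jitter_sd=0.0, member_seed=1)
        coords = fam[0].coords
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        np.testing.assert_allclose(steps, 3.8, atol=1e-9)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(coords))
        mask = np.abs(np.subtract.outer(range(30), range(30))) > 1
        assert d[mask].min() >= 4.0

    def test_bfactors_positive_and_shared(self):
        fam = generate_synthetic_family(3, 10, template_seed=2, jitter_sd=0.2, member_seed=4)
        assert np.all(fam[0].bfactors > 0)
        for member in fam[1:]:
            np.testing.assert_array_equal(member.bfactors, fam[0].bfactors)

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_family(1, 10, template_seed=1, jitter_sd=-0.1, member_seed=1)


def test_family_label_round_trip(tmp_path):
    labels = {"c1": "famA", "c2": "famB"}
    path = str(tmp_path / "labels.tsv")
    write_family_labels(labels, path)
    assert read_family_labels(path) == labels
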